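import numpy as np
import pandas as pd
import pytest

from circsplice import (
    ConditionEffect,
    SimulationDesign,
    TranscriptSignalSpec,
    classify_gain_loss,
    differential_splicing,
    extract_events,
    flag_spliced,
    generate_annotation,
    psi_per_sample,
    simulate_timecourse,
    spliced_genes,
)
from circsplice.annotation import LocalEvent
from conftest import make_matrix

from _oracles import oracle_mannwhitney_p


def _event(inc=("t1",), total=("t1", "t2"), etype="SE", gene="g"):
    return LocalEvent(
        event_id=f"{gene};{etype}:chr1:0-1:2-3:+",
        event_type=etype,
        gene_id=gene,
        chrom="chr1",
        strand="+",
        inclusion_transcripts=frozenset(inc),
        total_transcripts=frozenset(total),
    )


def _tpm(rows, feature_ids, n=4):
    return make_matrix(rows, 3.0 * np.arange(n), unit="TPM", feature_ids=feature_ids)


class TestPsiPerSample:
    def test_direct_ratio_and_edge_cases(self):
        tpm = _tpm([[9.0, 5.0, 0.0, 0.0], [1.0, 0.0, 0.0, 7.0]], ["t1", "t2"])
        mat, prof = psi_per_sample([_event()], tpm)
        row = mat.iloc[0]
        assert row.iloc[0] == pytest.approx(0.9)
        assert row.iloc[1] == pytest.approx(1.0)  # only inclusion expressed
        assert np.isnan(row.iloc[2])  # denominator zero -> undefined
        assert row.iloc[3] == pytest.approx(0.0)
        assert prof.iloc[0]["mean_psi"] == pytest.approx(np.nanmean(row))
        assert prof.iloc[0]["frac_defined"] == pytest.approx(0.75)

    def test_unknown_transcript_rejected(self):
        tpm = _tpm([[1.0] * 4], ["t1"])
        with pytest.raises(ValueError, match="absent"):
            psi_per_sample([_event()], tpm)

    def test_scale_invariance_is_exact(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.1, 50, size=(2, 4))
        m1 = _tpm(vals, ["t1", "t2"])
        m2 = _tpm(vals * rng.uniform(0.5, 20, 4), ["t1", "t2"])
        p1, _ = psi_per_sample([_event()], m1)
        p2, _ = psi_per_sample([_event()], m2)
        assert np.allclose(p1, p2)

    def test_complementary_forms_sum_to_one(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.0, 10, size=(2, 4))
        vals[:, 2] = 0.0  # undefined sample stays undefined for both
        tpm = _tpm(vals, ["t1", "t2"])
        fwd, _ = psi_per_sample([_event(inc=("t1",))], tpm)
        rev, _ = psi_per_sample([_event(inc=("t2",))], tpm)
        s = fwd.iloc[0] + rev.iloc[0]
        assert np.allclose(s.dropna(), 1.0)
        assert np.isnan(s.iloc[2])

    def test_programmed_inclusion_fraction_recovered(self):
        """A 30% inclusion isoform at noise_cv=0.05 yields mean PSI within
        0.02 of 0.3 over the 16-sample time course."""
        ann = generate_annotation(["SE"], 1, seed=1)
        gid = next(iter(ann.genes))
        t_inc, t_exc = sorted(ann.genes[gid].transcripts)  # t1 = inclusion form
        specs = [
            TranscriptSignalSpec(t_inc, 30.0, 0.0, 0.0, noise_cv=0.05),
            TranscriptSignalSpec(t_exc, 70.0, 0.0, 0.0, noise_cv=0.05),
        ]
        tpm, _ = simulate_timecourse(ann, SimulationDesign(seed=42), specs)
        events = extract_events(ann)
        _, prof = psi_per_sample(events, tpm)
        assert abs(prof.iloc[0]["mean_psi"] - 0.3) < 0.02


class TestSplicedFlag:
    def test_strict_boundaries(self):
        prof = pd.DataFrame(
            {
                "event_type": ["SE"] * 4,
                "gene_id": list("abcd"),
                "mean_psi": [0.10, 0.1000001, 0.9, 0.8999999],
                "frac_defined": [1.0] * 4,
            },
            index=[f"e{i}" for i in range(4)],
        )
        out = flag_spliced(prof)
        assert list(out["spliced"]) == [False, True, False, True]

    def test_straddling_fixture_matches_hand_flags(self):
        psis = [0.05, 0.1, 0.11, 0.3, 0.5, 0.7, 0.89, 0.9, 0.95, np.nan]
        prof = pd.DataFrame(
            {
                "event_type": ["RI"] * 10,
                "gene_id": [f"g{i}" for i in range(10)],
                "mean_psi": psis,
                "frac_defined": [1.0] * 10,
            },
            index=[f"e{i}" for i in range(10)],
        )
        hand = [False, False, True, True, True, True, True, False, False, False]
        assert list(flag_spliced(prof)["spliced"]) == hand

    def test_gene_sets_per_mode_and_missingness_gate(self):
        prof = pd.DataFrame(
            {
                "event_type": ["SE", "SE", "AF"],
                "gene_id": ["g1", "g2", "g1"],
                "mean_psi": [0.5, 0.5, 0.5],
                "frac_defined": [1.0, 0.4, 1.0],
            },
            index=["e1", "e2", "e3"],
        )
        sets = spliced_genes(flag_spliced(prof))
        assert sets["SE"] == {"g1"}  # g2 excluded: <50% defined samples
        assert sets["AF"] == {"g1"}
        assert sets["RI"] == set()


class TestGainLoss:
    def _sets(self, **kw):
        base = {t: set() for t in "A3 A5 AF AL MX RI SE".split()}
        base.update(kw)
        return base

    def test_loss_gain_shared(self):
        wt = self._sets(SE={"g1", "g2"}, AF=set())
        ko = self._sets(SE={"g2"}, AF={"g3"})
        out = classify_gain_loss(wt, ko).set_index(["gene_id", "event_type"])
        assert out.loc[("g1", "SE"), "status"] == "loss"
        assert out.loc[("g2", "SE"), "status"] == "shared"
        assert out.loc[("g3", "AF"), "status"] == "gain"

    def test_partition_of_universe(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        wt = self._sets(SE={g for g in genes if rng.random() < 0.5})
        ko = self._sets(SE={g for g in genes if rng.random() < 0.5})
        out = classify_gain_loss(wt, ko, expressed_genes=set(genes))
        se = out[out["event_type"] == "SE"]
        counts = se["status"].value_counts()
        assert counts.sum() == 30
        assert counts.get("gain", 0) == len(ko["SE"] - wt["SE"])
        assert counts.get("loss", 0) == len(wt["SE"] - ko["SE"])
        assert counts.get("shared", 0) == len(wt["SE"] & ko["SE"])

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError, match="keys"):
            classify_gain_loss({"SE": set()}, {"AF": set()})


class TestDifferentialSplicing:
    @staticmethod
    def _frame(rows, prefix):
        return pd.DataFrame(
            np.atleast_2d(rows),
            index=["e1"],
            columns=[f"{prefix}{i}" for i in range(np.atleast_2d(rows).shape[1])],
        )

    def test_identical_vectors(self):
        x = [0.2, 0.4, 0.3, 0.25, 0.35]
        out = differential_splicing(self._frame(x, "w"), self._frame(x, "k"))
        assert out.loc["e1", "p"] == 1.0
        assert out.loc["e1", "delta_psi"] == 0.0
        assert not out.loc["e1", "significant"]

    def test_fully_separated_vectors(self):
        wt = np.linspace(0.1, 0.3, 16)
        ko = np.linspace(0.6, 0.9, 16)
        out = differential_splicing(self._frame(wt, "w"), self._frame(ko, "k"))
        assert out.loc["e1", "p"] < 0.001
        assert out.loc["e1", "significant"]

    def test_small_n_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.uniform(0, 1, 5)
            y = rng.uniform(0, 1, 5)
            out = differential_splicing(self._frame(x, "w"), self._frame(y, "k"))
            assert out.loc["e1", "p"] == pytest.approx(
                oracle_mannwhitney_p(y, x), abs=1e-12
            )

    def test_insufficient_samples_marked_untestable(self):
        wt = self._frame([0.5, np.nan, np.nan, np.nan], "w")
        ko = self._frame([0.9, 0.8, 0.85, 0.8], "k")
        out = differential_splicing(wt, ko)
        assert out.loc["e1", "untestable"]
        assert np.isnan(out.loc["e1", "p"])


def test_gain_loss_recovered_from_programmed_switches():
    """Isoform switches pushing mean PSI across the 0.1/0.9 band produce
    the programmed gains and losses end to end (small version of the
    40-gene acceptance scenario)."""
    ann = generate_annotation(["SE"], 10, seed=9)
    gids = sorted(ann.genes)
    gain, loss = gids[:5], gids[5:]
    specs, effects = [], []
    for gid in gids:
        t1, t2 = sorted(ann.genes[gid].transcripts)
        if gid in gain:  # WT not spliced (0.97), KO spliced (0.5)
            specs += [
                TranscriptSignalSpec(t1, 97.0, noise_cv=0.02),
                TranscriptSignalSpec(t2, 3.0, noise_cv=0.02),
            ]
            effects.append(
                ConditionEffect("KO", "isoform_switch", gene_id=gid,
                                fractions={t1: 0.5, t2: 0.5})
            )
        else:  # WT spliced (0.5), KO not (0.95)
            specs += [
                TranscriptSignalSpec(t1, 50.0, noise_cv=0.02),
                TranscriptSignalSpec(t2, 50.0, noise_cv=0.02),
            ]
            effects.append(
                ConditionEffect("KO", "isoform_switch", gene_id=gid,
                                fractions={t1: 0.95, t2: 0.05})
            )
    design = SimulationDesign(conditions=["WT", "KO"], seed=9)
    tpm, _ = simulate_timecourse(ann, design, specs, effects)
    events = extract_events(ann)
    sets = {}
    for cond in ("WT", "KO"):
        _, prof = psi_per_sample(events, tpm.subset_condition(cond))
        sets[cond] = spliced_genes(prof)
    out = classify_gain_loss(sets["WT"], sets["KO"])
    status = out.set_index(["gene_id", "event_type"])["status"]
    assert all(status[(g, "SE")] == "gain" for g in gain)
    assert all(status[(g, "SE")] == "loss" for g in loss)
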