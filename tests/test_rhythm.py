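import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circsplice import (
    acrophase_bins,
    benjamini_hochberg,
    cosinor_fit,
    detect_rhythmic,
    gene_transcript_discordance,
    rhythm_test,
)
from conftest import make_matrix

from _oracles import oracle_cosinor_gridsearch, oracle_exhaustive_umbrella_p


class TestCosinor:
    def test_noiseless_model_recovered_exactly(self, grid16):
        y = 10 + 2 * np.cos(2 * np.pi * (grid16 - 6) / 24)
        f = cosinor_fit(y, grid16)
        assert abs(f.mesor - 10) < 1e-9
        assert abs(f.amplitude - 2) < 1e-9
        assert abs(f.acrophase - 6) < 1e-9
        assert abs(f.ramp - 0.2) < 1e-9

    def test_constant_series(self, grid16):
        f = cosinor_fit(np.full(16, 5.0), grid16)
        assert f.mesor == pytest.approx(5.0)
        assert f.amplitude == 0.0 and f.ramp == 0.0
        assert np.isnan(f.acrophase)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            cosinor_fit([1.0, 2.0, 3.0], [0.0, 8.0, 16.0])

    def test_noisy_fit_matches_gridsearch_oracle(self, grid16):
        rng = np.random.default_rng(11)
        y = 30 * (1 + 0.3 * np.cos(2 * np.pi * (grid16 - 17.2) / 24))
        y = y + rng.normal(0, 2.0, 16)
        f = cosinor_fit(y, grid16)
        m, a, phi = oracle_cosinor_gridsearch(y, grid16)
        assert abs(f.mesor - m) < 1e-6
        assert abs(f.amplitude - a) < 1e-6
        assert abs(f.acrophase - phi) < 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-30, 30),
        scale=st.floats(0.01, 100),
        phi=st.floats(0, 24, exclude_max=True),
    )
    def test_shift_equivariance_and_scale_invariance(self, shift, scale, phi):
        t = 9.0 + 3.0 * np.arange(16)
        y = 10 * (1 + 0.3 * np.cos(2 * np.pi * (t - phi) / 24))
        f0 = cosinor_fit(y, t)
        f_shift = cosinor_fit(y, t + shift)
        d = abs(f_shift.acrophase - (f0.acrophase + shift) % 24) % 24
        assert min(d, 24 - d) < 1e-6
        f_scale = cosinor_fit(scale * y, t)
        assert f_scale.mesor == pytest.approx(scale * f0.mesor, rel=1e-9)
        assert f_scale.amplitude == pytest.approx(scale * f0.amplitude, rel=1e-9)
        assert f_scale.ramp == pytest.approx(f0.ramp, rel=1e-9)


class TestRhythmTest:
    def test_perfect_sinusoid_hits_permutation_floor(self, grid16):
        y = 10 + 3 * np.cos(2 * np.pi * (grid16 - 12) / 24)
        p = rhythm_test(y, grid16, n_perm=1000, seed=0)
        assert p <= 0.01

    def test_constant_series_p_is_one(self, grid16):
        assert rhythm_test(np.full(16, 4.2), grid16, n_perm=500, seed=0) == 1.0

    def test_small_n_equals_exhaustive_enumeration(self):
        """The 8-point permutation p equals exhaustive enumeration over
        all phase-label assignments, computed by an independent naive
        implementation."""
        t = 3.0 * np.arange(8)
        rng = np.random.default_rng(4)
        for y in (
            np.array([1.0, 3, 5, 7, 8, 6, 4, 2]),
            rng.normal(10, 1, 8),
            np.array([2.0, 2, 5, 7, 7, 6, 4, 2]),  # with ties
        ):
            groups = list(range(8))
            assert rhythm_test(y, t) == pytest.approx(
                oracle_exhaustive_umbrella_p(list(y), groups), abs=1e-12
            )

    def test_monotone_transform_invariance(self, grid16):
        rng = np.random.default_rng(9)
        y = rng.lognormal(3, 0.4, 16)
        p0 = rhythm_test(y, grid16, n_perm=300, seed=7)
        for f in (np.exp, lambda v: 5 * v + 2, lambda v: v**3):
            assert rhythm_test(f(y), grid16, n_perm=300, seed=7) == p0

    def test_harmonic_f_method(self, grid16):
        y = 10 + 3 * np.cos(2 * np.pi * (grid16 - 12) / 24)
        noisy = y + np.random.default_rng(0).normal(0, 0.5, 16)
        assert rhythm_test(noisy, grid16, method="harmonic_F") < 1e-4
        assert rhythm_test(np.full(16, 2.0), grid16, method="harmonic_F") == 1.0

    def test_single_phase_group_rejected(self):
        with pytest.raises(ValueError, match="phase groups"):
            rhythm_test([1.0, 2, 3, 4], [0.0, 24, 48, 72])

    def test_too_few_permutations_rejected(self, grid16):
        with pytest.raises(ValueError, match="n_perm"):
            rhythm_test(np.arange(16.0), grid16, n_perm=50, exact=False)


class TestBenjaminiHochberg:
    def test_textbook_vector(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 50)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestDetectRhythmic:
    def test_ramp_gate_blocks_low_relative_amplitude(self, grid16):
        strong = 100 * (1 + 0.05 * np.cos(2 * np.pi * (grid16 - 3) / 24))
        weak_noise = strong + np.random.default_rng(1).normal(0, 0.2, 16)
        flat = np.full(16, 50.0)
        mat = make_matrix([weak_noise, flat], grid16)
        fits = detect_rhythmic(mat, n_perm=500, seed=1)
        f0 = fits.iloc[0]
        assert f0["q"] < 0.05 and f0["ramp"] < 0.1
        assert not f0["rhythmic"]

    def test_empty_matrix_rejected(self, grid16):
        mat = make_matrix(np.empty((0, 16)), grid16)
        with pytest.raises(ValueError, match="empty"):
            detect_rhythmic(mat)

    def test_flags_follow_q_and_ramp(self, grid16):
        rng = np.random.default_rng(3)
        rows = [
            40 * (1 + 0.4 * np.cos(2 * np.pi * (grid16 - phi) / 24))
            * np.exp(rng.normal(0, 0.05, 16))
            for phi in (0, 6, 12)
        ] + [40 * np.exp(rng.normal(0, 0.05, 16)) for _ in range(3)]
        fits = detect_rhythmic(make_matrix(rows, grid16), seed=3)
        expected = (fits["q"] < 0.05) & (fits["ramp"] >= 0.1)
        assert (fits["rhythmic"] == expected).all()
        assert fits["rhythmic"].iloc[:3].all()


class TestAcrophaseBins:
    def test_boundaries_and_oracle(self):
        rng = np.random.default_rng(8)
        phis = np.concatenate([[0.0, 23.9], rng.uniform(0, 24, 100)])
        fits = pd.DataFrame(
            {"acrophase": phis, "rhythmic": True},
            index=[f"f{i}" for i in range(len(phis))],
        )
        bins = acrophase_bins(fits)
        assert bins.sum() == len(phis)
        # direct per-value binning oracle
        oracle = {i: 0 for i in range(8)}
        for phi in phis:
            oracle[int(phi // 3)] += 1
        assert list(bins) == [oracle[i] for i in range(8)]
        assert bins.index[0] == "[0,3)" and bins.index[-1] == "[21,24)"

    def test_only_rhythmic_features_counted(self):
        fits = pd.DataFrame(
            {"acrophase": [1.0, 2.0], "rhythmic": [True, False]}, index=["a", "b"]
        )
        assert acrophase_bins(fits).sum() == 1


class TestDiscordance:
    @staticmethod
    def _fits(index, rhythmic):
        return pd.DataFrame({"rhythmic": rhythmic}, index=index)

    def test_class_assignment_and_errors(self):
        t2g = pd.DataFrame(
            {
                "transcript_id": ["t1", "t2", "t3", "t4", "t5"],
                "gene_id": ["gA", "gA", "gB", "gC", "gD"],
                "biotype": ["x"] * 5,
            }
        )
        tx = self._fits(["t1", "t2", "t3", "t4", "t5"], [True, True, True, False, False])
        genes = self._fits(["gA", "gB", "gC", "gD"], [False, True, True, False])
        out = gene_transcript_discordance(genes, tx, t2g)
        assert out.loc["gA", "class"] == "transcripts_only"
        assert out.loc["gB", "class"] == "both_rhythmic"
        assert out.loc["gC", "class"] == "gene_only"
        assert out.loc["gD", "class"] == "neither"
        with pytest.raises(ValueError, match="missing"):
            gene_transcript_discordance(genes.drop("gA"), tx, t2g)

    def test_mixed_simulation_matches_per_gene_recount(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(50)]
        tx_ids, gene_of = [], {}
        for g in genes:
            for j in range(rng.integers(1, 5)):
                tid = f"{g}.t{j}"
                tx_ids.append(tid)
                gene_of[tid] = g
        tx_flags = rng.random(len(tx_ids)) < 0.4
        gene_flags = rng.random(len(genes)) < 0.5
        t2g = pd.DataFrame(
            {"transcript_id": tx_ids, "gene_id": [gene_of[t] for t in tx_ids],
             "biotype": ["x"] * len(tx_ids)}
        )
        out = gene_transcript_discordance(
            self._fits(genes, gene_flags), self._fits(tx_ids, tx_flags), t2g
        )
        for g, gf in zip(genes, gene_flags):
            n_r = sum(tx_flags[i] for i, t in enumerate(tx_ids) if gene_of[t] == g)
            expected = (
                "both_rhythmic" if gf and n_r else
                "gene_only" if gf else
                "transcripts_only" if n_r else "neither"
            )
            assert out.loc[g, "class"] == expected
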