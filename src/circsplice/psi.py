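"""Percent-spliced-in (PSI) profiles, spliced-gene sets and gain/loss calls.

For a local event, per-sample PSI is the TPM of the inclusion transcripts
divided by the TPM of all event transcripts; it is undefined in samples
where no event transcript is expressed. An event is "spliced" in a
condition when its mean PSI over defined samples lies strictly inside
(psi_low, psi_high) = (0.1, 0.9). A gene is spliced by event mode E when
at least one of its type-E events is spliced. Comparing a knockout to its
control, a (gene, mode) spliced only in the knockout is a "gain", only in
the control a "loss". Differential splicing between conditions is tested
per event with a two-sided Mann-Whitney U on per-sample PSI values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import EVENT_TYPES, LocalEvent
from .expression import ExpressionMatrix

PSI_LOW = 0.1
PSI_HIGH = 0.9


def psi_per_sample(
    events: list[LocalEvent], tpm: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample PSI matrix (NaN = undefined) and per-event profile table.

    The profile table carries event_type, gene_id, mean PSI over defined
    samples, the defined-sample fraction and the spliced flag.
    """
    tpm.require_unit("TPM")
    known = set(tpm.feature_ids)
    rows, meta = [], []
    for ev in events:
        missing = (ev.total_transcripts - known) or None
        if missing:
            raise ValueError(
                f"{ev.event_id}: transcripts absent from TPM matrix: "
                f"{sorted(missing)}"
            )
        inc = tpm.data.loc[sorted(ev.inclusion_transcripts)].sum(axis=0)
        tot = tpm.data.loc[sorted(ev.total_transcripts)].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(tot > 0, inc / tot, np.nan)
        rows.append(psi)
        meta.append((ev.event_id, ev.event_type, ev.gene_id))
    index = pd.Index([m[0] for m in meta], name="event_id")
    psi_matrix = pd.DataFrame(rows, index=index, columns=tpm.sample_ids)
    profiles = pd.DataFrame(
        {
            "event_type": [m[1] for m in meta],
            "gene_id": [m[2] for m in meta],
            "mean_psi": psi_matrix.mean(axis=1),
            "frac_defined": psi_matrix.notna().mean(axis=1),
        },
        index=index,
    )
    return psi_matrix, flag_spliced(profiles)


def flag_spliced(
    profiles: pd.DataFrame, psi_low: float = PSI_LOW, psi_high: float = PSI_HIGH
) -> pd.DataFrame:
    """Add the strict-inequality spliced flag: psi_low < mean PSI < psi_high."""
    out = profiles.copy()
    out["spliced"] = (out["mean_psi"] > psi_low) & (out["mean_psi"] < psi_high)
    out.loc[out["mean_psi"].isna(), "spliced"] = False
    return out


def spliced_genes(
    profiles: pd.DataFrame, min_frac_defined: float = 0.5
) -> dict[str, set[str]]:
    """Genes spliced per event mode (>=1 spliced event of that mode).

    Events with fewer than ``min_frac_defined`` defined samples are
    excluded from the condition's gene sets.
    """
    usable = profiles[profiles["frac_defined"] >= min_frac_defined]
    out: dict[str, set[str]] = {et: set() for et in EVENT_TYPES}
    for et, sub in usable[usable["spliced"]].groupby("event_type"):
        out[str(et)] = set(sub["gene_id"])
    return out


def classify_gain_loss(
    wt_gene_sets: dict[str, set[str]],
    ko_gene_sets: dict[str, set[str]],
    expressed_genes: set[str] | None = None,
    circadian_genes: set[str] | None = None,
    coding_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Gain/loss/shared/absent status per (gene, event mode) in KO vs control.

    ``absent`` rows are only produced when ``expressed_genes`` is given
    (genes expressed but spliced in neither condition). Each record is
    annotated with whether the gene has a circadian transcript and a
    protein-coding transcript, for stratified summaries.
    """
    if set(wt_gene_sets) != set(ko_gene_sets):
        raise ValueError("event-type keys differ between WT and KO gene sets")
    circadian_genes = circadian_genes or set()
    coding_genes = coding_genes or set()
    records = []
    for et in sorted(wt_gene_sets):
        wt, ko = wt_gene_sets[et], ko_gene_sets[et]
        universe = wt | ko | (expressed_genes or set())
        for gid in sorted(universe):
            if gid in ko and gid not in wt:
                status = "gain"
            elif gid in wt and gid not in ko:
                status = "loss"
            elif gid in wt and gid in ko:
                status = "shared"
            else:
                status = "absent"
            records.append(
                (
                    gid,
                    et,
                    status,
                    gid in circadian_genes,
                    gid in coding_genes,
                )
            )
    return pd.DataFrame(
        records,
        columns=[
            "gene_id",
            "event_type",
            "status",
            "has_circadian_transcript",
            "has_protein_coding_transcript",
        ],
    )


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # every labelling ties; no evidence either way
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def differential_splicing(
    psi_wt: pd.DataFrame,
    psi_ko: pd.DataFrame,
    alpha: float = 0.05,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney test of per-sample PSI, KO vs control.

    Events with fewer than ``min_samples`` defined PSI values in either
    condition are marked untestable (p = NaN). ``delta_psi`` is
    mean PSI(KO) - mean PSI(WT) over defined samples. The exact U
    distribution is used when both groups have <= 8 tie-free values,
    otherwise the normal approximation with midrank tie correction.
    """
    common = psi_wt.index.intersection(psi_ko.index)
    records = []
    for ev in common:
        x = psi_ko.loc[ev].dropna().to_numpy(float)
        y = psi_wt.loc[ev].dropna().to_numpy(float)
        delta = x.mean() - y.mean() if len(x) and len(y) else np.nan
        if len(x) < min_samples or len(y) < min_samples:
            records.append((ev, delta, np.nan, False, True))
            continue
        p = _mannwhitney(x, y)
        records.append((ev, delta, p, p < alpha, False))
    return pd.DataFrame(
        records,
        columns=["event_id", "delta_psi", "p", "significant", "untestable"],
    ).set_index("event_id")
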