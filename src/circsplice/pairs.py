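"""Differential rhythmicity of within-gene transcript isoform pairs.

Every unordered pair of rhythmic transcripts of the same gene is tested
for a difference in rhythm shape: each series is standardized to unit
mesor (dividing by the fitted M so that pure expression-level offsets do
not register) and a joint harmonic regression with pair-indicator
interaction terms is fit; the F-test of equal cosine/sine coefficients
(2 numerator df) gives the p-value. The circular phase difference
``delta_phase = min(|phi_a - phi_b|, period - |phi_a - phi_b|)`` lies in
[0, period/2]; pairs with BH q < alpha and delta_phase >= 3 h are the
phase-shifted class, binned into <3, [3,6), [6,9) and >=9 h.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .rhythm import benjamini_hochberg, cosinor_fit

PHASE_BIN_LABELS = ["<3", "[3,6)", "[6,9)", ">=9"]


def enumerate_pairs(rhythm_table: pd.DataFrame, tx2gene: pd.DataFrame) -> pd.DataFrame:
    """All unordered within-gene pairs of rhythmic transcripts.

    Transcript ids are ordered lexicographically within a pair; genes with
    fewer than two rhythmic transcripts contribute nothing.
    """
    rhythmic = rhythm_table.index[rhythm_table["rhythmic"]]
    mapping = tx2gene[tx2gene["transcript_id"].isin(rhythmic)]
    rows = [
        (gid, a, b)
        for gid, sub in mapping.groupby("gene_id")
        for a, b in combinations(sorted(sub["transcript_id"]), 2)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "transcript_a", "transcript_b"])


def circular_phase_difference(phi_a: float, phi_b: float, period: float = 24.0) -> float:
    d = abs(phi_a - phi_b) % period
    return min(d, period - d)


def pair_test(
    series_a,
    series_b,
    times,
    period: float = 24.0,
    standardize_mesor: bool = True,
) -> tuple[float, float, float]:
    """Test one isoform pair; returns (p, delta_phase, amplitude_ratio).

    ``amplitude_ratio`` is amplitude(b) / amplitude(a) on the
    mesor-standardized scale (i.e. the rAMP ratio) under the given
    argument order.
    """
    ya = np.asarray(series_a, float)
    yb = np.asarray(series_b, float)
    t = np.asarray(times, float)
    fit_a = cosinor_fit(ya, t, period)
    fit_b = cosinor_fit(yb, t, period)
    if fit_a.mesor <= 0 or fit_b.mesor <= 0:
        raise ValueError("pair test requires positive fitted mesors")
    if fit_a.amplitude == 0 and fit_b.amplitude == 0:
        raise ValueError("both series are constant; no rhythm to compare")
    if standardize_mesor:
        ya = ya / fit_a.mesor
        yb = yb / fit_b.mesor
    w = 2.0 * np.pi / period
    cos_t, sin_t = np.cos(w * t), np.sin(w * t)
    y = np.concatenate([ya, yb])
    ind = np.concatenate([np.zeros_like(ya), np.ones_like(yb)])
    cc, ss = np.concatenate([cos_t, cos_t]), np.concatenate([sin_t, sin_t])
    x_full = np.column_stack(
        [np.ones_like(y), ind, cc, ss, cc * ind, ss * ind]
    )
    x_null = x_full[:, :4]  # common rhythm shape, separate intercepts
    rss_full = _rss(x_full, y)
    rss_null = _rss(x_null, y)
    df2 = y.size - x_full.shape[1]
    if rss_full <= 1e-12 * max(rss_null, 1.0):
        p = 1.0 if rss_null - rss_full <= 1e-12 * max(rss_null, 1.0) else 0.0
    else:
        f = ((rss_null - rss_full) / 2.0) / (rss_full / df2)
        p = float(stats.f.sf(f, 2, df2))
    if np.isnan(fit_a.acrophase) or np.isnan(fit_b.acrophase):
        dphi = np.nan
    else:
        dphi = circular_phase_difference(fit_a.acrophase, fit_b.acrophase, period)
    ratio = (
        (fit_b.amplitude / fit_b.mesor) / (fit_a.amplitude / fit_a.mesor)
        if fit_a.amplitude > 0
        else np.inf
    )
    return p, float(dphi), float(ratio)


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def evaluate_pairs(
    pairs: pd.DataFrame,
    matrix: ExpressionMatrix,
    period: float = 24.0,
    standardize_mesor: bool = True,
) -> pd.DataFrame:
    """Run ``pair_test`` for every candidate pair against the matrix."""
    records = []
    times = matrix.times
    for row in pairs.itertuples(index=False):
        ya = matrix.data.loc[row.transcript_a].to_numpy(float)
        yb = matrix.data.loc[row.transcript_b].to_numpy(float)
        fa = cosinor_fit(ya, times, period)
        fb = cosinor_fit(yb, times, period)
        p, dphi, ratio = pair_test(ya, yb, times, period, standardize_mesor)
        records.append(
            (
                row.gene_id,
                row.transcript_a,
                row.transcript_b,
                fa.acrophase,
                fb.acrophase,
                dphi,
                ratio,
                p,
            )
        )
    return pd.DataFrame(
        records,
        columns=[
            "gene_id",
            "transcript_a",
            "transcript_b",
            "phase_a",
            "phase_b",
            "delta_phase",
            "amp_ratio",
            "p",
        ],
    )


def _phase_bin(dphi: float) -> str:
    if np.isnan(dphi):
        return "NA"
    if dphi < 3:
        return "<3"
    if dphi < 6:
        return "[3,6)"
    if dphi < 9:
        return "[6,9)"
    return ">=9"


def classify_pairs(
    results: pd.DataFrame,
    tx2gene: pd.DataFrame | None = None,
    alpha_q: float = 0.05,
    min_shift: float = 3.0,
) -> pd.DataFrame:
    """BH-correct pair p-values, bin phase differences, label biotypes.

    Adds columns q, differentially_rhythmic (q < alpha_q), phase_shifted
    (differentially rhythmic AND delta_phase >= min_shift), phase_bin and,
    when a tx2gene map with biotypes is given, the unordered biotype_pair
    label (e.g. ``protein_coding/retained_intron``).
    """
    out = results.copy()
    out["q"] = benjamini_hochberg(out["p"]) if len(out) else []
    out["differentially_rhythmic"] = out["q"] < alpha_q
    out["phase_shifted"] = out["differentially_rhythmic"] & (
        out["delta_phase"] >= min_shift
    )
    out["phase_bin"] = out["delta_phase"].map(_phase_bin)
    if tx2gene is not None and "biotype" in tx2gene.columns:
        bmap = tx2gene.set_index("transcript_id")["biotype"]
        out["biotype_pair"] = [
            "/".join(sorted((bmap.get(a, "unknown"), bmap.get(b, "unknown"))))
            for a, b in zip(out["transcript_a"], out["transcript_b"])
        ]
    return out
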