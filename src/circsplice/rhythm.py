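"""Detection of ~24 h rhythmic features in time-course expression.

Two rhythmicity tests are provided. ``rank_umbrella`` is a nonparametric
test in the spirit of RAIN: sampling times are folded modulo the period
into phase groups, and a Mack-Wolfe umbrella rank statistic is maximized
over candidate peak groups, with each candidate evaluated on the circular
rotation that places the antipodal (trough) group first; the null is a
seeded permutation of sample labels, or exhaustive enumeration of all
value assignments when the series is short enough (n <= 8). The
``harmonic_F`` alternative is a parametric F-test of the single-harmonic
cosinor model against an intercept-only model.

Rhythm parameters come from the cosinor model
``y(t) = M + A*cos(2*pi*(t - phi)/period)``: mesor M, amplitude A,
acrophase phi (time of fitted peak, hours modulo the period) and the
relative amplitude rAMP = A/M. A feature is called rhythmic when its
BH-adjusted p-value is below ``alpha_q`` (default 0.05) and rAMP is at
least ``min_ramp`` (default 0.1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

PHASE_SENTINEL = np.nan
_EXACT_MAX_N = 8  # 8! = 40320 assignments is the largest exhaustive null


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase: float  # hours in [0, period); NaN when amplitude == 0
    ramp: float


def _design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(times), np.cos(w * times), np.sin(w * times)])


def cosinor_fit(values, times, period: float = 24.0) -> CosinorFit:
    """Least-squares single-harmonic cosinor fit of one series."""
    y = np.asarray(values, float)
    t = np.asarray(times, float)
    if y.shape != t.shape:
        raise ValueError("values and times must have equal length")
    if np.unique(t).size < 4:
        raise ValueError("cosinor fit requires at least 4 distinct timepoints")
    x = _design(t, period)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    m, a, b = beta
    amp = float(np.hypot(a, b))
    scale = max(1.0, abs(m))
    if amp < 1e-12 * scale:
        return CosinorFit(float(m), 0.0, PHASE_SENTINEL, 0.0)
    phi = (period / (2.0 * np.pi)) * np.arctan2(b, a) % period
    ramp = amp / m if m > 0 else np.nan
    return CosinorFit(float(m), amp, float(phi), float(ramp))


def _cosinor_fit_matrix(
    values: np.ndarray, times: np.ndarray, period: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized cosinor over rows of ``values``; returns (M, A, phi, F-p)."""
    x = _design(times, period)
    beta, *_ = np.linalg.lstsq(x, values.T, rcond=None)
    m, a, b = beta
    amp = np.hypot(a, b)
    phi = (period / (2.0 * np.pi)) * np.arctan2(b, a) % period
    scale = np.maximum(1.0, np.abs(m))
    flat = amp < 1e-12 * scale
    amp = np.where(flat, 0.0, amp)
    phi = np.where(flat, PHASE_SENTINEL, phi)
    fitted = (x @ beta).T
    rss1 = np.sum((values - fitted) ** 2, axis=1)
    rss0 = np.sum((values - values.mean(axis=1, keepdims=True)) ** 2, axis=1)
    n = values.shape[1]
    df2 = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / 2.0) / (rss1 / df2)
    p = np.where(
        rss0 <= 1e-300,
        1.0,  # exactly constant series carries no rhythm evidence
        np.where(rss1 <= 1e-12 * np.maximum(rss0, 1.0), 0.0, stats.f.sf(f, 2, df2)),
    )
    return m, amp, phi, np.clip(p, 1e-300, 1.0)


# ---------------------------------------------------------------------------
# rank-umbrella permutation machinery


def _phase_groups(times: np.ndarray, period: float) -> np.ndarray:
    """Group index per sample after folding times modulo the period."""
    folded = np.round(np.mod(times, period), 9)
    uniq = np.unique(folded)
    if uniq.size < 2:
        raise ValueError("fewer than 2 phase groups after folding")
    return np.searchsorted(uniq, folded)


def _umbrella_layout(sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per candidate peak group: pair-weight matrix, null mean and sd.

    For peak group p the k groups (in circular phase order) are rotated so
    that the group antipodal to p comes first; the Mack-Wolfe statistic
    counts concordant pairs rising to the peak and falling after it. Null
    moments use the tie-free Mack-Wolfe formulas (identical standardization
    is applied to observed and permuted data, so midrank ties only enter
    through the common statistic).
    """
    k = sizes.size
    weights = np.zeros((k, k, k))
    mu = np.zeros(k)
    sd = np.zeros(k)
    for p in range(k):
        start = (p + k // 2 + 1) % k
        order = [(start + i) % k for i in range(k)]
        q = order.index(p)
        for i in range(k):
            for j in range(i + 1, k):
                if j <= q:
                    weights[p, order[i], order[j]] = 1.0  # rising limb
                elif i >= q:
                    weights[p, order[j], order[i]] = 1.0  # falling limb
                # pairs straddling the peak (i < q < j) are not scored
        n1 = float(sizes[order[: q + 1]].sum())
        n2 = float(sizes[order[q:]].sum())
        ntot = float(sizes.sum())
        npk = float(sizes[p])
        sq = float((sizes.astype(float) ** 2).sum())
        cb = float((sizes.astype(float) ** 2 * (2 * sizes + 3)).sum())
        mu[p] = (n1**2 + n2**2 - sq - npk**2) / 4.0
        var = (
            2 * (n1**3 + n2**3)
            + 3 * (n1**2 + n2**2)
            - cb
            - npk**2 * (2 * npk + 3)
            + 12 * npk * n1 * n2
            - 12 * npk**2 * ntot
        ) / 72.0
        sd[p] = np.sqrt(max(var, 1e-300))
    return weights, mu, sd


def _umbrella_stats(
    values: np.ndarray, group_onehot: np.ndarray, layout
) -> np.ndarray:
    """Max standardized umbrella statistic for each row of ``values``."""
    weights, mu, sd = layout
    lt = (values[:, :, None] < values[:, None, :]).astype(float)
    eq = (values[:, :, None] == values[:, None, :]).astype(float)
    np.einsum("bxx->bx", eq)[:] = 0.0  # a sample does not tie with itself
    c = lt + 0.5 * eq
    u = np.einsum("xi,bxy,yj->bij", group_onehot, c, group_onehot, optimize=True)
    a = np.einsum("bij,pij->bp", u, weights, optimize=True)
    return ((a - mu) / sd).max(axis=1)


def _exact_umbrella_p(y: np.ndarray, onehot: np.ndarray, layout) -> float:
    perms = np.array(list(itertools.permutations(y)))
    stats_all = _umbrella_stats(perms, onehot, layout)
    obs = _umbrella_stats(y[None, :], onehot, layout)[0]
    return float(np.mean(stats_all >= obs - 1e-12))


def rhythm_test(
    values,
    times,
    period: float = 24.0,
    method: str = "rank_umbrella",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    exact: bool | None = None,
) -> float:
    """One-feature test of ~period-hour rhythmicity; returns the p-value.

    ``exact=None`` enumerates all n! value assignments when n <= 8 and
    otherwise falls back to ``n_perm`` seeded random permutations with the
    add-one convention p = (1 + #{T* >= T}) / (1 + n_perm). An exactly
    constant series yields p = 1 by convention.
    """
    y = np.asarray(values, float)
    t = np.asarray(times, float)
    if method == "harmonic_F":
        return float(_cosinor_fit_matrix(y[None, :], t, period)[3][0])
    if method != "rank_umbrella":
        raise ValueError(f"unknown rhythm test method {method!r}")
    groups = _phase_groups(t, period)
    k = groups.max() + 1
    sizes = np.bincount(groups, minlength=k)
    layout = _umbrella_layout(sizes)
    onehot = np.eye(k)[groups].astype(float).reshape(len(y), k)
    if exact is None:
        exact = len(y) <= _EXACT_MAX_N
    if exact:
        return _exact_umbrella_p(y, onehot, layout)
    if n_perm < 100:
        raise ValueError("rank_umbrella requires n_perm >= 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    obs = _umbrella_stats(y[None, :], onehot, layout)[0]
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    null = _umbrella_stats(perms, onehot, layout)
    return float((1.0 + np.sum(null >= obs - 1e-12)) / (1.0 + n_perm))


def detect_rhythmic(
    matrix: ExpressionMatrix,
    period: float = 24.0,
    alpha_q: float = 0.05,
    min_ramp: float = 0.1,
    method: str = "rank_umbrella",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature rhythm fits, tests, BH correction and the rhythmic flag.

    The matrix must hold unlogged CPM (or TPM at gene level for the
    gene-vs-transcript comparison); BH is applied over all features of the
    matrix. Returns a table indexed by feature id with columns mesor,
    amplitude, acrophase, ramp, p, q, rhythmic.
    """
    if matrix.data.empty:
        raise ValueError("cannot detect rhythmicity in an empty matrix")
    values = matrix.data.to_numpy(float)
    times = matrix.times
    mesor, amp, phi, p_harm = _cosinor_fit_matrix(values, times, period)
    with np.errstate(divide="ignore", invalid="ignore"):
        ramp = np.where(mesor > 0, amp / mesor, np.nan)
    if method == "harmonic_F":
        p = p_harm
    else:
        groups = _phase_groups(times, period)
        k = groups.max() + 1
        layout = _umbrella_layout(np.bincount(groups, minlength=k))
        onehot = np.eye(k)[groups].astype(float)
        n = values.shape[1]
        exact = n <= _EXACT_MAX_N
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(values.shape[0])
        p = np.empty(values.shape[0])
        for i in range(values.shape[0]):
            y = values[i]
            if exact:
                p[i] = _exact_umbrella_p(y, onehot, layout)
                continue
            rng = np.random.default_rng(children[i])
            obs = _umbrella_stats(y[None, :], onehot, layout)[0]
            perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
            null = _umbrella_stats(perms, onehot, layout)
            p[i] = (1.0 + np.sum(null >= obs - 1e-12)) / (1.0 + n_perm)
    q = benjamini_hochberg(p)
    rhythmic = (q < alpha_q) & (np.nan_to_num(ramp) >= min_ramp)
    return pd.DataFrame(
        {
            "mesor": mesor,
            "amplitude": amp,
            "acrophase": phi,
            "ramp": ramp,
            "p": p,
            "q": q,
            "rhythmic": rhythmic,
        },
        index=matrix.feature_ids,
    )


def benjamini_hochberg(p) -> np.ndarray:
    """BH-adjusted q-values over one family of tests."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def acrophase_bins(
    fits: pd.DataFrame, bin_width: float = 3.0, period: float = 24.0
) -> pd.Series:
    """Histogram of rhythmic acrophases in [0,w),[w,2w),... bins."""
    rhythmic = fits[fits["rhythmic"]]
    edges = np.arange(0.0, period + bin_width / 2, bin_width)
    counts, _ = np.histogram(rhythmic["acrophase"].dropna(), bins=edges)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    return pd.Series(counts, index=labels, name="n_rhythmic")


def gene_transcript_discordance(
    gene_fits: pd.DataFrame, transcript_fits: pd.DataFrame, tx2gene: pd.DataFrame
) -> pd.DataFrame:
    """Classify each gene by gene- vs transcript-level rhythmicity.

    ``both_rhythmic``: rhythmic gene with >=1 rhythmic transcript;
    ``gene_only``: rhythmic gene whose transcripts are all arrhythmic
    (arrhythmic transcripts summing to a rhythmic gene); ``transcripts_only``:
    arrhythmic gene with >=1 rhythmic transcript (e.g. antiphase isoforms
    cancelling at gene level); ``neither`` otherwise.
    """
    mapping = tx2gene[tx2gene["transcript_id"].isin(transcript_fits.index)]
    records = []
    for gid, sub in mapping.groupby("gene_id"):
        if gid not in gene_fits.index:
            raise ValueError(f"gene {gid} missing from gene-level fits")
        n_tx = len(sub)
        n_rhythmic_tx = int(
            transcript_fits.loc[sub["transcript_id"], "rhythmic"].sum()
        )
        gene_rhythmic = bool(gene_fits.loc[gid, "rhythmic"])
        if gene_rhythmic and n_rhythmic_tx > 0:
            cls = "both_rhythmic"
        elif gene_rhythmic:
            cls = "gene_only"
        elif n_rhythmic_tx > 0:
            cls = "transcripts_only"
        else:
            cls = "neither"
        records.append((gid, cls, n_rhythmic_tx, n_tx))
    return pd.DataFrame(
        records,
        columns=["gene_id", "class", "n_rhythmic_transcripts", "n_transcripts"],
    ).set_index("gene_id")
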