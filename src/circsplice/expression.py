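"""Expression containers and normalization.

Transcript-level abundance tables (features x samples) are bound to a
sample sheet recording condition, sampling time in hours and replicate.
Counts are normalized by trimmed-mean-of-M-values (TMM) factors and
expressed as counts per million of the effective library size; rhythm
detection downstream consumes unlogged CPM while PSI consumes TPM, so the
unit of every matrix is tracked and enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ["condition", "time_h", "replicate"]


@dataclass
class ExpressionMatrix:
    """Non-negative feature x sample table with a sample sheet and a unit."""

    data: pd.DataFrame
    samples: pd.DataFrame
    unit: str  # "counts" | "TPM" | "CPM"

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not self.data.columns.equals(pd.Index(self.samples.index)):
            if not set(self.data.columns) <= set(self.samples.index):
                raise ValueError("sample sheet does not match matrix columns")
            # sheet may cover a superset (e.g. a per-condition matrix slice)
            self.samples = self.samples.loc[self.data.columns]

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def times(self) -> np.ndarray:
        return self.samples["time_h"].to_numpy(float)

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["condition"] == condition]
        if len(keep) == 0:
            raise ValueError(f"no samples for condition {condition!r}")
        return ExpressionMatrix(self.data[keep], self.samples.loc[keep], self.unit)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[feature_ids])

    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise ValueError(f"expected a {unit} matrix, got {self.unit}")

    def write(self, matrix_path, sample_sheet_path=None) -> None:
        self.data.to_csv(matrix_path, sep="\t", index_label="feature_id")
        if sample_sheet_path is not None:
            self.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


def read_matrix(matrix_path, sample_sheet_path, unit: str) -> ExpressionMatrix:
    data = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    samples = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return ExpressionMatrix(data, samples, unit)


@dataclass
class NormalizationFactors:
    """TMM factors (geometric mean 1) and raw library sizes per sample."""

    factors: pd.Series
    lib_sizes: pd.Series
    ref_sample: str = ""

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")


def _choose_reference(y: np.ndarray, lib: np.ndarray) -> int:
    # sample whose upper-quartile count fraction is closest to the mean
    f75 = np.percentile(y / lib, 75, axis=0)
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positive features with the reference")
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = m.size
    # rank-based symmetric trimming: logratio_trim/2 and sum_trim/2 per tail
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    lo_m, hi_m = n * logratio_trim / 2, n * (1 - logratio_trim / 2)
    lo_a, hi_a = n * sum_trim / 2, n * (1 - sum_trim / 2)
    keep = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep]
    f = np.sum(m[keep] * inv_w) / np.sum(inv_w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: ExpressionMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    Per sample against a reference, M (log2 count-fraction ratio) and A
    (average log2 abundance) are computed over features positive in both;
    30% of M (15% per tail) and 5% of A (2.5% per tail) are trimmed and
    the factor is 2 to the inverse-asymptotic-variance weighted mean of
    the surviving M. Factors are rescaled to geometric mean one.
    """
    counts.require_unit("counts")
    y = counts.data.to_numpy(float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive library size")
    if ref_sample is None:
        ref_idx = _choose_reference(y, lib)
    else:
        ref_idx = int(counts.sample_ids.get_loc(ref_sample))
    ref = y[:, ref_idx]
    n_ref = lib[ref_idx]
    factors = np.array(
        [
            1.0
            if k == ref_idx
            else _tmm_pair(y[:, k], ref, lib[k], n_ref, logratio_trim, sum_trim)
            for k in range(y.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.sample_ids, name="tmm_factor"),
        lib_sizes=pd.Series(lib, index=counts.sample_ids, name="lib_size"),
        ref_sample=str(counts.sample_ids[ref_idx]),
    )


def cpm(counts: ExpressionMatrix, factors: NormalizationFactors) -> ExpressionMatrix:
    """Counts per million of the effective (TMM-scaled) library size."""
    counts.require_unit("counts")
    eff = factors.lib_sizes.loc[counts.sample_ids] * factors.factors.loc[
        counts.sample_ids
    ]
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    data = counts.data.div(eff, axis=1) * 1e6
    return ExpressionMatrix(data, counts.samples, "CPM")


def filter_low_expression(
    cpm_matrix: ExpressionMatrix,
    counts: ExpressionMatrix,
    threshold: float = 0.5,
    refresh_factors: bool = True,
    factors: NormalizationFactors | None = None,
) -> tuple[ExpressionMatrix, NormalizationFactors, ExpressionMatrix]:
    """Retain features with mean CPM >= threshold and renormalize.

    Returns (filtered counts, factors, refreshed CPM). By default TMM
    factors and library sizes are recomputed from the retained features;
    with ``refresh_factors=False`` the supplied pre-filter ``factors`` are
    reused and only the CPM table is re-subset.
    """
    cpm_matrix.require_unit("CPM")
    counts.require_unit("counts")
    if not cpm_matrix.feature_ids.equals(counts.feature_ids):
        raise ValueError("CPM and counts matrices must share features")
    keep = cpm_matrix.data.mean(axis=1) >= threshold
    if not keep.any():
        raise ValueError("low-expression filter removed every feature")
    kept_counts = counts.subset_features(counts.feature_ids[keep])
    if refresh_factors:
        new_factors = tmm_factors(kept_counts)
    else:
        if factors is None:
            raise ValueError("refresh_factors=False requires the original factors")
        new_factors = factors
    return kept_counts, new_factors, cpm(kept_counts, new_factors)


def summarize_to_gene(
    matrix: ExpressionMatrix, tx2gene: pd.DataFrame
) -> ExpressionMatrix:
    """Sum transcript rows into gene rows (tximport-style, txOut=FALSE)."""
    mapping = tx2gene.set_index("transcript_id")["gene_id"]
    missing = matrix.feature_ids.difference(mapping.index)
    if len(missing):
        raise ValueError(
            f"transcripts missing from tx2gene map: {sorted(missing)[:10]}"
        )
    gene_ids = mapping.loc[matrix.feature_ids]
    data = matrix.data.groupby(gene_ids.to_numpy()).sum()
    data.index.name = matrix.data.index.name
    return ExpressionMatrix(data, matrix.samples, matrix.unit)
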