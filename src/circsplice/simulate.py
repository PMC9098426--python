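"""Synthetic time-course transcript expression with known ground truth.

The generator emulates the study design the pipeline targets: cell-line
time courses sampled every 3 h over 45 h (16 timepoints starting at 9 h,
one replicate each), a wild-type-like reference condition and knockout
conditions carrying programmable perturbations (loss of rhythm, phase
shift, amplitude scaling, isoform-usage switch, expression knockout).
Each expressed transcript follows a cosinor signal
``mesor * (1 + rAMP * cos(2*pi*(t - acrophase)/period))`` with
multiplicative log-normal noise of a given coefficient of variation.
Counts are drawn Poisson around means proportional to TPM times the
summed exon length, scaled to a configurable library size. Toy gene
models realizing each of the seven local AS event modes are generated on
both strands.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .annotation import EVENT_TYPES, Gene, Transcript, TranscriptAnnotation
from .expression import ExpressionMatrix

DEFAULT_LIBRARY_SIZE = 1_000_000.0


@dataclass
class SimulationDesign:
    """Sampling grid and condition layout of a simulated experiment."""

    n_timepoints: int = 16
    t_start: float = 9.0
    dt: float = 3.0
    n_replicates: int = 1
    conditions: list[str] = field(default_factory=lambda: ["WT"])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise ValueError("need at least 4 timepoints")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition required")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_timepoints)


@dataclass
class TranscriptSignalSpec:
    """Cosinor parameters of one transcript's deterministic signal."""

    transcript_id: str
    mesor: float
    rel_amplitude: float = 0.0
    acrophase: float = 0.0
    period: float = 24.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.mesor < 0:
            raise ValueError("mesor must be non-negative")
        if not 0.0 <= self.rel_amplitude <= 1.0:
            raise ValueError("rel_amplitude must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def expected(self, times: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi / self.period
        return self.mesor * (
            1.0 + self.rel_amplitude * np.cos(w * (times - self.acrophase))
        )


@dataclass
class ConditionEffect:
    """A perturbation applied to targets in exactly one non-reference condition.

    ``kind`` is one of rhythm_loss, phase_shift (param = hours),
    amplitude_scale (param = factor), expression_knockout, or
    isoform_switch. An isoform switch redistributes the gene's total
    expected abundance across its transcripts by the fractions in
    ``fractions`` (summing to 1), leaving the gene-level series unchanged.
    """

    condition: str
    kind: str
    targets: list[str] = field(default_factory=list)  # transcript ids
    gene_id: str | None = None  # for isoform_switch
    param: float = 0.0
    fractions: dict[str, float] | None = None

    _KINDS = (
        "rhythm_loss",
        "phase_shift",
        "amplitude_scale",
        "isoform_switch",
        "expression_knockout",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "isoform_switch":
            if not self.fractions or self.gene_id is None:
                raise ValueError("isoform_switch needs gene_id and fractions")
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("isoform_switch fractions must sum to 1")


# ---------------------------------------------------------------------------
# toy annotation generator

_EXON = 100  # toy exon length
_GAP = 200  # toy intron length


def _event_gene(gid: str, chrom: str, strand: str, etype: str, offset: int) -> Gene:
    """Two transcripts realizing exactly one event of ``etype``."""

    def ex(i: int) -> tuple[int, int]:
        s = offset + i * (_EXON + _GAP)
        return (s, s + _EXON)

    t1_id, t2_id = f"{gid}.t1", f"{gid}.t2"
    if etype == "SE":
        t1, t2 = [ex(0), ex(1), ex(2)], [ex(0), ex(2)]
    elif etype == "RI":
        e0, e1 = ex(0), ex(1)
        t1, t2 = [e0, e1], [(e0[0], e1[1])]
    elif etype == "A5":
        e0, e1 = ex(0), ex(1)
        longer = (e0[0], e0[1] + 60) if strand == "+" else e0
        shorter = e0 if strand == "+" else (e0[0], e0[1] + 60)
        # donor side varies with strand; build overlap on the correct side
        if strand == "+":
            t1, t2 = [longer, e1], [shorter, e1]
        else:
            e1a, e1b = (e1[0] - 60, e1[1]), e1
            t1, t2 = [e0, e1a], [e0, e1b]
    elif etype == "A3":
        e0, e1 = ex(0), ex(1)
        if strand == "+":
            t1, t2 = [e0, (e1[0] - 60, e1[1])], [e0, e1]
        else:
            t1, t2 = [(e0[0], e0[1] + 60), e1], [e0, e1]
    elif etype == "MX":
        t1, t2 = [ex(0), ex(1), ex(3)], [ex(0), ex(2), ex(3)]
    elif etype == "AF":
        if strand == "+":
            t1, t2 = [ex(0), ex(2)], [ex(1), ex(2)]
        else:
            t1, t2 = [ex(0), ex(2)], [ex(0), ex(1)]
    elif etype == "AL":
        if strand == "+":
            t1, t2 = [ex(0), ex(1)], [ex(0), ex(2)]
        else:
            t1, t2 = [ex(1), ex(2)], [ex(0), ex(2)]
    else:
        raise ValueError(f"unknown event code {etype!r}")
    gene = Gene(gid, chrom, strand)
    gene.transcripts[t1_id] = Transcript(t1_id, gid, "protein_coding", t1)
    gene.transcripts[t2_id] = Transcript(t2_id, gid, "protein_coding", t2)
    return gene


def generate_annotation(
    event_menu=EVENT_TYPES, n_genes_per_type: int = 1, seed: int = 0
) -> TranscriptAnnotation:
    """Toy genes, two transcripts each, realizing the requested event modes.

    Genes alternate strand and are laid out on one chromosome with random
    start offsets; coordinates are valid (sorted, disjoint exons) by
    construction.
    """
    unknown = set(event_menu) - set(EVENT_TYPES)
    if unknown:
        raise ValueError(f"unknown event codes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    ann = TranscriptAnnotation()
    cursor = 0
    i = 0
    for etype in event_menu:
        for _ in range(n_genes_per_type):
            strand = "+" if i % 2 == 0 else "-"
            gid = f"G_{etype}_{i:03d}"
            offset = cursor + int(rng.integers(0, 500))
            gene = _event_gene(gid, "chrS", strand, etype, offset)
            ann.genes[gid] = gene
            cursor = max(e for t in gene.transcripts.values() for _, e in t.exons)
            cursor += 1000
            i += 1
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# time-course simulation


def _apply_effects(
    base: dict[str, TranscriptSignalSpec],
    effects: list[ConditionEffect],
    condition: str,
    annotation: TranscriptAnnotation,
    times: np.ndarray,
) -> dict[str, np.ndarray]:
    """Noise-free expected TPM series per transcript for one condition."""
    specs = {tid: spec for tid, spec in base.items()}
    expected = {tid: spec.expected(times) for tid, spec in specs.items()}
    for eff in effects:
        if eff.condition != condition:
            continue
        if eff.kind == "isoform_switch":
            gene = annotation.genes.get(eff.gene_id)
            if gene is None:
                raise ValueError(f"isoform_switch: unknown gene {eff.gene_id!r}")
            members = sorted(gene.transcripts)
            unknown = set(eff.fractions) - set(members)
            if unknown:
                raise ValueError(
                    f"isoform_switch: transcripts not in {eff.gene_id}: "
                    f"{sorted(unknown)}"
                )
            total = np.sum([expected[tid] for tid in members], axis=0)
            for tid in members:
                expected[tid] = total * eff.fractions.get(tid, 0.0)
            continue
        for tid in eff.targets:
            if tid not in specs:
                raise ValueError(f"effect targets unknown transcript {tid!r}")
            s = specs[tid]
            if eff.kind == "rhythm_loss":
                s2 = TranscriptSignalSpec(tid, s.mesor, 0.0, 0.0, s.period, s.noise_cv)
            elif eff.kind == "phase_shift":
                s2 = TranscriptSignalSpec(
                    tid,
                    s.mesor,
                    s.rel_amplitude,
                    (s.acrophase + eff.param) % s.period,
                    s.period,
                    s.noise_cv,
                )
            elif eff.kind == "amplitude_scale":
                s2 = TranscriptSignalSpec(
                    tid,
                    s.mesor,
                    min(1.0, s.rel_amplitude * eff.param),
                    s.acrophase,
                    s.period,
                    s.noise_cv,
                )
            else:  # expression_knockout
                s2 = TranscriptSignalSpec(tid, 0.0, 0.0, 0.0, s.period, s.noise_cv)
            specs[tid] = s2
            expected[tid] = s2.expected(times)
    return expected


def simulate_timecourse(
    annotation: TranscriptAnnotation,
    design: SimulationDesign,
    signal_specs: list[TranscriptSignalSpec],
    effects: list[ConditionEffect] | None = None,
    library_size: float = DEFAULT_LIBRARY_SIZE,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Simulate transcript TPM and count matrices across all conditions.

    Deterministic given ``design.seed``. The noise-free expected value
    follows each spec's cosine; multiplicative log-normal noise with
    log-sd sqrt(log(1 + cv^2)) (unit mean) is applied per observation.
    Counts are Poisson with per-sample means proportional to
    TPM x transcript length, normalized to ``library_size``.
    """
    effects = effects or []
    known = set(annotation.transcripts)
    base = {}
    for spec in signal_specs:
        if spec.transcript_id not in known:
            raise ValueError(f"signal spec for unknown transcript {spec.transcript_id!r}")
        base[spec.transcript_id] = spec
    missing = known - set(base)
    if missing:
        raise ValueError(
            f"transcripts lack signal specs: {sorted(missing)[:10]}"
        )
    for eff in effects:
        if eff.condition == design.conditions[0]:
            raise ValueError("effects must target a non-reference condition")
        if eff.condition not in design.conditions:
            raise ValueError(f"effect condition {eff.condition!r} not in design")

    rng = np.random.default_rng(design.seed)
    tids = sorted(base)
    lengths = np.array([annotation.transcripts[t].length for t in tids], float)
    times = design.times
    cols, sheet, tpm_cols, count_cols = [], [], [], []
    for cond in design.conditions:
        expected = _apply_effects(base, effects, cond, annotation, times)
        exp_mat = np.vstack([expected[t] for t in tids])  # tx x timepoints
        cv = np.array([base[t].noise_cv for t in tids])
        sigma = np.sqrt(np.log1p(cv**2))
        for rep in range(1, design.n_replicates + 1):
            for j, t in enumerate(times):
                mu = exp_mat[:, j]
                noise = np.exp(
                    rng.normal(-0.5 * sigma**2, sigma, size=len(tids))
                )
                tpm = mu * np.where(cv > 0, noise, 1.0)
                tpm_cols.append(tpm)
                reads = tpm * lengths
                tot = reads.sum()
                lam = library_size * reads / tot if tot > 0 else np.zeros_like(reads)
                count_cols.append(rng.poisson(lam).astype(float))
                cols.append(f"{cond}_T{t:.6g}_R{rep}")
                sheet.append((cond, float(t), rep))
    samples = pd.DataFrame(
        sheet, columns=["condition", "time_h", "replicate"], index=pd.Index(cols, name="sample_id")
    )
    index = pd.Index(tids, name="feature_id")
    tpm_df = pd.DataFrame(np.column_stack(tpm_cols), index=index, columns=cols)
    count_df = pd.DataFrame(np.column_stack(count_cols), index=index, columns=cols)
    return (
        ExpressionMatrix(tpm_df, samples, "TPM"),
        ExpressionMatrix(count_df, samples, "counts"),
    )


def write_ground_truth(
    path,
    signal_specs: list[TranscriptSignalSpec],
    effects: list[ConditionEffect],
    extra: dict | None = None,
) -> None:
    """Dump the programmed truth (specs + effects) as JSON for assertions."""
    payload = {
        "signal_specs": [asdict(s) for s in signal_specs],
        "effects": [asdict(e) for e in effects],
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
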