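"""End-to-end orchestration of the circadian splicing pipeline.

Stages: normalization (TMM/CPM, low-expression filter) -> rhythm
detection per condition at transcript and gene level -> local AS event
extraction -> PSI, spliced-gene sets, gain/loss and differential splicing
per knockout-vs-reference comparison -> within-condition isoform-pair
differential rhythmicity -> gene-set summaries. Every stage writes its
TSV under the output directory; a JSON manifest records parameters and
seeds and a JSON summary the headline counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import read_gtf, write_ioe
from .events import extract_events
from .expression import (
    ExpressionMatrix,
    cpm,
    filter_low_expression,
    read_matrix,
    summarize_to_gene,
    tmm_factors,
)
from .genesets import hallmark_association, load_gene_sets, sf_rhythm_matrix
from .pairs import classify_pairs, enumerate_pairs, evaluate_pairs
from .psi import (
    classify_gain_loss,
    differential_splicing,
    psi_per_sample,
    spliced_genes,
)
from .rhythm import acrophase_bins, detect_rhythmic, gene_transcript_discordance

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and condition roles for one pipeline run."""

    annotation: str = ""
    tpm: str = ""
    counts: str = ""
    sample_sheet: str = ""
    splicing_factors: str | None = None
    hallmarks: str | None = None
    reference_condition: str = ""
    period: float = 24.0
    alpha_q: float = 0.05
    min_ramp: float = 0.1
    psi_low: float = 0.1
    psi_high: float = 0.9
    min_shift_h: float = 3.0
    diffsplice_alpha: float = 0.05
    cpm_threshold: float = 0.5
    method: str = "rank_umbrella"
    n_perm: int = 1000
    seed: int = 0
    refresh_factors: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi_low < self.psi_high <= 1.0:
            raise ValueError("need 0 <= psi_low < psi_high <= 1")
        if not 0.0 <= self.min_shift_h <= self.period / 2:
            raise ValueError("min_shift_h must lie in [0, period/2]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the summary dict written to summary.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        log.info("stage %-12s t=%.1fs", name, time.time() - t0)

    stage("inputs")
    annotation = read_gtf(config.annotation)
    tx2gene = annotation.tx2gene()
    tx2gene.to_csv(out / "tx2gene.tsv", sep="\t", index=False)
    tpm = read_matrix(config.tpm, config.sample_sheet, "TPM")
    counts = read_matrix(config.counts, config.sample_sheet, "counts")
    conditions = list(dict.fromkeys(counts.samples["condition"]))
    reference = config.reference_condition or conditions[0]
    if reference not in conditions:
        raise ValueError(f"reference condition {reference!r} not in sample sheet")
    comparisons = [c for c in conditions if c != reference]

    stage("normalize")
    cpm_by_cond: dict[str, ExpressionMatrix] = {}
    for cond in conditions:
        c_counts = counts.subset_condition(cond)
        factors = tmm_factors(c_counts)
        raw_cpm = cpm(c_counts, factors)
        _f_counts, factors2, f_cpm = filter_low_expression(
            raw_cpm,
            c_counts,
            threshold=config.cpm_threshold,
            refresh_factors=config.refresh_factors,
            factors=factors,
        )
        cpm_by_cond[cond] = f_cpm
        pd.DataFrame(
            {"tmm_factor": factors2.factors, "lib_size": factors2.lib_sizes}
        ).to_csv(out / f"normalization_{cond}.tsv", sep="\t", index_label="sample_id")
        f_cpm.write(out / f"cpm_{cond}.tsv")

    stage("rhythm")
    tx_fits: dict[str, pd.DataFrame] = {}
    gene_fits: dict[str, pd.DataFrame] = {}
    discordance: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        f_cpm = cpm_by_cond[cond]
        fits = detect_rhythmic(
            f_cpm,
            period=config.period,
            alpha_q=config.alpha_q,
            min_ramp=config.min_ramp,
            method=config.method,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        tx_fits[cond] = fits
        _write(fits, out / f"rhythm_transcripts_{cond}.tsv")
        gene_cpm = summarize_to_gene(f_cpm, tx2gene)
        gfits = detect_rhythmic(
            gene_cpm,
            period=config.period,
            alpha_q=config.alpha_q,
            min_ramp=config.min_ramp,
            method=config.method,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        gene_fits[cond] = gfits
        _write(gfits, out / f"rhythm_genes_{cond}.tsv")
        disc = gene_transcript_discordance(gfits, fits, tx2gene)
        discordance[cond] = disc
        _write(disc, out / f"discordance_{cond}.tsv")
        _write(
            acrophase_bins(fits, period=config.period).to_frame(),
            out / f"acrophase_bins_{cond}.tsv",
        )

    stage("events")
    events = extract_events(annotation)
    write_ioe(events, out / "events.ioe")

    stage("psi")
    psi_mats, profiles, genesets_by_cond = {}, {}, {}
    for cond in conditions:
        mat, prof = psi_per_sample(events, tpm.subset_condition(cond))
        prof = prof.copy()
        prof["spliced"] = (prof["mean_psi"] > config.psi_low) & (
            prof["mean_psi"] < config.psi_high
        )
        prof.loc[prof["mean_psi"].isna(), "spliced"] = False
        psi_mats[cond], profiles[cond] = mat, prof
        _write(mat, out / f"psi_{cond}.tsv")
        _write(prof, out / f"psi_profiles_{cond}.tsv")
        genesets_by_cond[cond] = spliced_genes(prof)

    coding_genes = set(
        tx2gene.loc[tx2gene["biotype"] == "protein_coding", "gene_id"]
    )
    gain_loss: dict[str, pd.DataFrame] = {}
    diffsplice: dict[str, pd.DataFrame] = {}
    for cond in comparisons:
        circadian = _circadian_genes(tx_fits[reference], tx2gene) | _circadian_genes(
            tx_fits[cond], tx2gene
        )
        gl = classify_gain_loss(
            genesets_by_cond[reference],
            genesets_by_cond[cond],
            circadian_genes=circadian,
            coding_genes=coding_genes,
        )
        gain_loss[cond] = gl
        _write(gl, out / f"gain_loss_{cond}_vs_{reference}.tsv", index=False)
        ds = differential_splicing(
            psi_mats[reference], psi_mats[cond], alpha=config.diffsplice_alpha
        )
        diffsplice[cond] = ds
        _write(ds, out / f"diffsplice_{cond}_vs_{reference}.tsv")

    stage("diffrhythm")
    pair_tables: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        cand = enumerate_pairs(tx_fits[cond], tx2gene)
        res = evaluate_pairs(cand, cpm_by_cond[cond], period=config.period)
        res = classify_pairs(
            res, tx2gene, alpha_q=config.alpha_q, min_shift=config.min_shift_h
        )
        pair_tables[cond] = res
        _write(res, out / f"isoform_pairs_{cond}.tsv", index=False)

    stage("genesets")
    summary: dict = {
        "conditions": conditions,
        "reference_condition": reference,
        "n_rhythmic_transcripts": {
            c: int(tx_fits[c]["rhythmic"].sum()) for c in conditions
        },
        "n_rhythmic_genes": {
            c: int(gene_fits[c]["rhythmic"].sum()) for c in conditions
        },
        "discordance_classes": {
            c: discordance[c]["class"].value_counts().to_dict() for c in conditions
        },
        "gain_loss_counts": {
            c: gain_loss[c]
            .groupby(["event_type", "status"])
            .size()
            .unstack(fill_value=0)
            .to_dict()
            for c in comparisons
        },
        "n_differentially_spliced": {
            c: int(diffsplice[c]["significant"].sum()) for c in comparisons
        },
        "isoform_pairs": {
            c: {
                "n_pairs_tested": int(len(pair_tables[c])),
                "n_differentially_rhythmic": int(
                    pair_tables[c]["differentially_rhythmic"].sum()
                ),
                "n_phase_shifted": int(pair_tables[c]["phase_shifted"].sum()),
                "phase_bins": pair_tables[c]
                .loc[pair_tables[c]["phase_shifted"], "phase_bin"]
                .value_counts()
                .to_dict(),
            }
            for c in conditions
        },
    }
    if config.splicing_factors:
        sf = load_gene_sets(config.splicing_factors, "splicing_factors")
        sf_genes = set().union(*sf.sets.values())
        matrix, counts_df, lost = sf_rhythm_matrix(
            tx_fits, sf_genes, tx2gene, reference=reference
        )
        _write(matrix, out / "sf_rhythm_matrix.tsv")
        _write(counts_df, out / "sf_rhythm_counts.tsv")
        summary["sf_rhythmic_counts"] = counts_df["n_sf_genes_rhythmic"].to_dict()
        summary["sf_lost_in_all_ko"] = sorted(lost)
    if config.hallmarks:
        hm = load_gene_sets(config.hallmarks, "hallmarks")
        classes = {
            f"phase_shifted_{c}": set(
                pair_tables[c].loc[pair_tables[c]["phase_shifted"], "gene_id"]
            )
            for c in conditions
        }
        for c in comparisons:
            gl = gain_loss[c]
            classes[f"gain_{c}"] = set(gl.loc[gl["status"] == "gain", "gene_id"])
            classes[f"loss_{c}"] = set(gl.loc[gl["status"] == "loss", "gene_id"])
        mem, counts_hm = hallmark_association(classes, hm)
        _write(mem, out / "hallmark_membership.tsv", index=False)
        _write(counts_hm, out / "hallmark_counts.tsv", index=False)
        summary["hallmark_counts"] = {
            f"{r['class']}|{r['hallmark']}": int(r["n_genes"])
            for _, r in counts_hm.iterrows()
        }

    manifest = {
        "package": "circsplice",
        "version": __version__,
        "parameters": asdict(config),
        "conditions": conditions,
        "reference_condition": reference,
        "n_events": len(events),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    stage("done")
    return summary


def _circadian_genes(fits: pd.DataFrame, tx2gene: pd.DataFrame) -> set[str]:
    rhythmic = set(fits.index[fits["rhythmic"]])
    return set(tx2gene.loc[tx2gene["transcript_id"].isin(rhythmic), "gene_id"])
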