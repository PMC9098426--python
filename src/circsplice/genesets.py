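"""Gene-set mapping, over-representation tests and summary tables.

Curated sets (splicing factors, cancer hallmarks) are read from 2-column
TSV (set name, gene id) or GMT files. Over-representation of a query
gene list within a universe is the upper-tail hypergeometric probability
P(X >= k), BH-corrected across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .rhythm import benjamini_hochberg

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


def load_gene_sets(paths, provenance: str = "") -> GeneSetCollection:
    """Read one or more TSV/GMT gene-set files into a collection.

    Duplicated genes within a set are collapsed with a warning; gene ids
    are case-preserving.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    sets: dict[str, set[str]] = {}
    for path in paths:
        text = open(path).read().rstrip("\n")
        if not text:
            raise ValueError(f"{path}: empty gene-set file")
        if str(path).endswith(".gmt"):
            for line in text.split("\n"):
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: GMT line needs name, desc, genes")
                name, genes = fields[0], fields[2:]
                _add(sets, name, genes, path)
        else:
            for line in text.split("\n"):
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}: expected 2 columns (set, gene)")
                sets.setdefault(fields[0], set())
                if fields[1] in sets[fields[0]]:
                    log.warning("%s: duplicate gene %s in set %s", path, fields[1], fields[0])
                sets[fields[0]].add(fields[1])
    return GeneSetCollection(sets, provenance)


def _add(sets: dict, name: str, genes: list[str], path) -> None:
    uniq = set(genes)
    if len(uniq) < len(genes):
        log.warning("%s: duplicated genes collapsed in set %s", path, name)
    sets.setdefault(name, set()).update(uniq)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            for gene in sorted(collection.sets[name]):
                fh.write(f"{name}\t{gene}\n")


def hypergeom_enrichment(
    query: set[str], universe: set[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` per set."""
    stray = set(query) - set(universe)
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    n_u, n_q = len(universe), len(query)
    records = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & set(universe)
        k = len(set(query) & members)
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_u, big_k, n_q)) if big_k else 1.0
        records.append((name, k, n_q, big_k, n_u, p))
    df = pd.DataFrame(
        records, columns=["set", "overlap", "query_size", "set_size", "universe", "p"]
    )
    df["q"] = benjamini_hochberg(df["p"]) if len(df) else []
    return df.set_index("set")


def sf_rhythm_matrix(
    rhythm_tables: dict[str, pd.DataFrame],
    sf_genes: set[str],
    tx2gene: pd.DataFrame,
    reference: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Categorical SF-rhythmicity matrix across conditions.

    Returns (boolean gene x condition matrix: gene has >=1 rhythmic
    transcript; per-condition counts of rhythmic SF genes/transcripts;
    the set of SFs rhythmic in the reference condition but in none of the
    others). SF genes with no expressed transcript in any condition are
    excluded.
    """
    conds = list(rhythm_tables)
    if reference is None:
        reference = conds[0]
    gmap = tx2gene.set_index("transcript_id")["gene_id"]
    flags: dict[str, dict[str, bool]] = {}
    counts = []
    for cond in conds:
        tab = rhythm_tables[cond]
        genes_of = gmap.loc[gmap.index.intersection(tab.index)]
        sf_tx = genes_of[genes_of.isin(sf_genes)]
        rhythmic_tx = tab.loc[sf_tx.index, "rhythmic"]
        per_gene = rhythmic_tx.groupby(sf_tx.to_numpy()).any()
        for gid in sf_tx.unique():
            flags.setdefault(gid, {})[cond] = bool(per_gene.get(gid, False))
        counts.append(
            (
                cond,
                int(per_gene.sum()),
                int(rhythmic_tx.sum()),
            )
        )
    matrix = pd.DataFrame.from_dict(flags, orient="index").fillna(False)
    matrix = matrix.reindex(columns=conds, fill_value=False).sort_index()
    count_df = pd.DataFrame(
        counts, columns=["condition", "n_sf_genes_rhythmic", "n_sf_transcripts_rhythmic"]
    ).set_index("condition")
    others = [c for c in conds if c != reference]
    lost = {
        gid
        for gid in matrix.index
        if matrix.loc[gid, reference] and not any(matrix.loc[gid, c] for c in others)
    } if others else set()
    return matrix, count_df, lost


def hallmark_association(
    class_gene_lists: dict[str, set[str]], collection: GeneSetCollection
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hallmark memberships per gene and counts per result class.

    Genes belonging to no hallmark set are excluded from the membership
    table.
    """
    memberships = []
    for cls in sorted(class_gene_lists):
        for gid in sorted(class_gene_lists[cls]):
            hits = sorted(n for n, s in collection.sets.items() if gid in s)
            for h in hits:
                memberships.append((cls, gid, h))
    mem_df = pd.DataFrame(memberships, columns=["class", "gene_id", "hallmark"])
    if len(mem_df):
        counts = (
            mem_df.groupby(["class", "hallmark"]).size().rename("n_genes").reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["class", "hallmark", "n_genes"])
    return mem_df, counts
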