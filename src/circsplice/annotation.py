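"""Transcript annotation model plus GTF and .ioe interchange.

Exon intervals are stored 0-based half-open (``[start, end)``); GTF I/O
converts from/to the 1-based inclusive convention at the file boundary.
Alternative-splicing events are identified by deterministic string ids of
the form ``gene;TYPE:chrom:coords:strand`` so that event tables from
different runs can be joined.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

EVENT_TYPES = ("A3", "A5", "AF", "AL", "MX", "RI", "SE")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class Transcript:
    """One transcript: an ordered set of disjoint exon intervals on a gene."""

    transcript_id: str
    gene_id: str
    biotype: str = "unknown"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def sort_exons(self) -> None:
        self.exons.sort()

    @property
    def length(self) -> int:
        """Summed exon length (effective-length proxy)."""
        return sum(e - s for s, e in self.exons)

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Introns as (end of upstream exon, start of downstream exon)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)


@dataclass
class TranscriptAnnotation:
    """Gene/transcript/exon models, the substrate for local AS events."""

    genes: dict[str, Gene] = field(default_factory=dict)

    @property
    def transcripts(self) -> dict[str, Transcript]:
        out: dict[str, Transcript] = {}
        for g in self.genes.values():
            out.update(g.transcripts)
        return out

    def validate(self) -> None:
        for g in self.genes.values():
            if g.strand not in ("+", "-"):
                raise ValueError(f"gene {g.gene_id}: invalid strand {g.strand!r}")
            for t in g.transcripts.values():
                t.sort_exons()
                for (s, e) in t.exons:
                    if e <= s:
                        raise ValueError(
                            f"transcript {t.transcript_id}: empty exon [{s}, {e})"
                        )
                for (_, e1), (s2, _) in zip(t.exons, t.exons[1:]):
                    if s2 < e1:
                        raise ValueError(
                            f"transcript {t.transcript_id}: overlapping exons"
                        )

    def tx2gene(self) -> pd.DataFrame:
        rows = [
            (t.transcript_id, g.gene_id, t.biotype)
            for g in sorted(self.genes.values(), key=lambda g: g.gene_id)
            for t in sorted(g.transcripts.values(), key=lambda t: t.transcript_id)
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype"])


@dataclass(frozen=True)
class LocalEvent:
    """One local alternative-splicing event with its transcript sets.

    ``inclusion_transcripts`` is a strict subset of ``total_transcripts``;
    PSI for the event is the inclusion share of the total TPM.
    """

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    inclusion_transcripts: frozenset[str]
    total_transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty inclusion set")
        if not self.inclusion_transcripts < self.total_transcripts:
            raise ValueError(
                f"{self.event_id}: inclusion set must be a strict subset of total"
            )


# ---------------------------------------------------------------------------
# GTF I/O


def _parse_attributes(attr: str, lineno: int) -> dict[str, str]:
    pairs = dict(_ATTR_RE.findall(attr))
    if not pairs:
        raise ValueError(f"GTF line {lineno}: malformed attribute field {attr!r}")
    return pairs


def read_gtf(path) -> TranscriptAnnotation:
    """Read exon features from a GTF file into an annotation.

    Non-exon features are ignored; a missing ``transcript_biotype``
    attribute defaults to ``"unknown"``. Coordinates are converted from
    1-based inclusive to 0-based half-open.
    """
    ann = TranscriptAnnotation()
    n_exons = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"GTF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"GTF line {lineno}: non-integer coordinate") from exc
            if end < start:
                raise ValueError(f"GTF line {lineno}: end {end} < start {start}")
            attrs = _parse_attributes(attr, lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ValueError(
                    f"GTF line {lineno}: exon missing gene_id/transcript_id"
                )
            gid, tid = attrs["gene_id"], attrs["transcript_id"]
            biotype = attrs.get("transcript_biotype", "unknown")
            gene = ann.genes.setdefault(gid, Gene(gid, chrom, strand))
            if gene.strand != strand:
                raise ValueError(
                    f"GTF line {lineno}: strand {strand!r} conflicts with "
                    f"gene {gid} on {gene.strand!r}"
                )
            tx = gene.transcripts.setdefault(tid, Transcript(tid, gid, biotype))
            tx.exons.append((start - 1, end))  # to 0-based half-open
            n_exons += 1
    if n_exons == 0:
        log.warning("no exon features found in %s; annotation is empty", path)
    ann.validate()
    return ann


def write_gtf(annotation: TranscriptAnnotation, path) -> None:
    """Write exon features (gene_id, transcript_id, transcript_biotype)."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                for s, e in sorted(tx.exons):
                    attrs = (
                        f'gene_id "{gid}"; transcript_id "{tid}"; '
                        f'transcript_biotype "{tx.biotype}";'
                    )
                    fh.write(
                        f"{gene.chrom}\tcircsplice\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# SUPPA-style .ioe I/O

_IOE_COLUMNS = [
    "seqname",
    "gene_id",
    "event_id",
    "inclusion_transcripts",
    "total_transcripts",
]


def write_ioe(events: list[LocalEvent], path) -> None:
    rows = [
        (
            ev.chrom,
            ev.gene_id,
            ev.event_id,
            ",".join(sorted(ev.inclusion_transcripts)),
            ",".join(sorted(ev.total_transcripts)),
        )
        for ev in events
    ]
    pd.DataFrame(rows, columns=_IOE_COLUMNS).to_csv(path, sep="\t", index=False)


def _event_type_from_id(event_id: str) -> str:
    # gene;TYPE:chrom:coords:strand
    try:
        return event_id.split(";", 1)[1].split(":", 1)[0]
    except IndexError as exc:
        raise ValueError(f"malformed event_id {event_id!r}") from exc


def read_ioe(path) -> list[LocalEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_IOE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ioe file missing columns: {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        inclusion = frozenset(row.inclusion_transcripts.split(","))
        total = frozenset(row.total_transcripts.split(","))
        if not inclusion < total:
            raise ValueError(
                f"{row.event_id}: inclusion transcripts not a strict "
                "subset of total transcripts"
            )
        strand = row.event_id.rsplit(":", 1)[-1]
        events.append(
            LocalEvent(
                event_id=row.event_id,
                event_type=_event_type_from_id(row.event_id),
                gene_id=row.gene_id,
                chrom=row.seqname,
                strand=strand,
                inclusion_transcripts=inclusion,
                total_transcripts=total,
            )
        )
    return events
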