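"""Enumeration of the seven local alternative-splicing event modes.

Events are discovered from exon/junction signatures within each gene, so a
single event can be supported by more than two transcripts: the inclusion
and total transcript sets are unions over every transcript of the gene
compatible with the corresponding form.

Strand semantics follow transcription direction: A5/A3 (alternative donor
vs acceptor), AF/AL (alternative first vs last exon) and the MX inclusion
convention all flip between ``+`` and ``-`` genes. Inclusion-form
conventions: SE — the exon-containing form; RI — the intron-retaining
form; A5/A3 — the form with the longer exonic extension (shorter intron);
MX — the form using the transcription-upstream internal exon; AF/AL — the
form whose alternative terminal exon lies more distal from the shared
exon. Boundary matching is strict (coordinates must agree exactly).
"""

from __future__ import annotations

from .annotation import Gene, LocalEvent, Transcript, TranscriptAnnotation


def _tx_index(tx: Transcript) -> dict:
    exons = sorted(tx.exons)
    return {
        "tx": tx,
        "exons": exons,
        "exon_set": set(exons),
        "junctions": [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)],
    }


def _internal_exons(ix: dict):
    """Yield (a, b, c, d): internal exon [b, c) with flanking junctions (a,b), (c,d)."""
    exons = ix["exons"]
    for i in range(1, len(exons) - 1):
        b, c = exons[i]
        a = exons[i - 1][1]
        d = exons[i + 1][0]
        yield a, b, c, d


def _first_exon(ix: dict, strand: str):
    """Transcription-first exon and its junction into the adjacent exon.

    Returns ((s, e), shared_coord) where shared_coord is the boundary of the
    neighbouring (shared) exon the first exon splices into, or None for
    single-exon transcripts.
    """
    exons = ix["exons"]
    if len(exons) < 2:
        return None
    if strand == "+":
        return exons[0], exons[1][0]  # shared exon start
    return exons[-1], exons[-2][1]  # shared exon end


def _last_exon(ix: dict, strand: str):
    exons = ix["exons"]
    if len(exons) < 2:
        return None
    if strand == "+":
        return exons[-1], exons[-2][1]
    return exons[0], exons[1][0]


def _overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return max(x[0], y[0]) < min(x[1], y[1])


def _gene_events(gene: Gene) -> list[LocalEvent]:
    idx = {tid: _tx_index(tx) for tid, tx in gene.transcripts.items()}
    tids = sorted(idx)
    chrom, strand, gid = gene.chrom, gene.strand, gene.gene_id
    jset = {tid: set(idx[tid]["junctions"]) for tid in tids}

    # signature -> (event_type, inclusion-membership fn, total-membership fn, id coords)
    sigs: dict[tuple, tuple] = {}

    def add(etype: str, key: tuple, coords: str, member_inc, member_exc) -> None:
        sigs.setdefault((etype, key), (coords, member_inc, member_exc))

    for ti in tids:
        for tj in tids:
            if ti == tj:
                continue
            ii, ij = idx[ti], idx[tj]

            # SE: internal exon of ti skipped by a junction of tj
            for a, b, c, d in _internal_exons(ii):
                if (a, d) in jset[tj]:
                    add(
                        "SE",
                        (a, b, c, d),
                        f"{a}-{b}:{c}-{d}",
                        lambda ix, a=a, b=b, c=c, d=d: (
                            (b, c) in ix["exon_set"]
                            and (a, b) in set(ix["junctions"])
                            and (c, d) in set(ix["junctions"])
                        ),
                        lambda ix, a=a, d=d: (a, d) in set(ix["junctions"]),
                    )

            # RI: a junction of ti retained within a single exon of tj
            for k, (a, b) in enumerate(ii["junctions"]):
                s = ii["exons"][k][0]
                e = ii["exons"][k + 1][1]
                if (s, e) in ij["exon_set"]:
                    add(
                        "RI",
                        (s, a, b, e),
                        f"{s}:{a}-{b}:{e}",
                        lambda ix, s=s, e=e: (s, e) in ix["exon_set"],
                        lambda ix, s=s, a=a, b=b, e=e: (
                            (s, a) in ix["exon_set"]
                            and (b, e) in ix["exon_set"]
                            and (a, b) in set(ix["junctions"])
                        ),
                    )

            # A5/A3: junction pairs sharing one endpoint, flanking exons overlap
            for k1, (d1, a1) in enumerate(ii["junctions"]):
                for k2, (d2, a2) in enumerate(ij["junctions"]):
                    if a1 == a2 and d1 != d2:
                        # alternative boundary on the genomic-left exon
                        exl1 = ii["exons"][k1]
                        exl2 = ij["exons"][k2]
                        if not _overlap(exl1, exl2):
                            continue
                        dlo, dhi = sorted((d1, d2))
                        etype = "A5" if strand == "+" else "A3"
                        # longer exonic extension = larger end = shorter intron
                        add(
                            etype,
                            ("R", dlo, dhi, a1),
                            f"{dhi}-{a1}:{dlo}-{a1}",
                            lambda ix, d=dhi, a=a1: (d, a) in set(ix["junctions"]),
                            lambda ix, d=dlo, a=a1: (d, a) in set(ix["junctions"]),
                        )
                    if d1 == d2 and a1 != a2:
                        exr1 = ii["exons"][k1 + 1]
                        exr2 = ij["exons"][k2 + 1]
                        if not _overlap(exr1, exr2):
                            continue
                        alo, ahi = sorted((a1, a2))
                        etype = "A3" if strand == "+" else "A5"
                        add(
                            etype,
                            ("L", d1, alo, ahi),
                            f"{d1}-{alo}:{d1}-{ahi}",
                            lambda ix, d=d1, a=alo: (d, a) in set(ix["junctions"]),
                            lambda ix, d=d1, a=ahi: (d, a) in set(ix["junctions"]),
                        )

            # MX: two non-overlapping internal exons sharing outer junction ends
            for a1, b1, c1, d1 in _internal_exons(ii):
                for a2, b2, c2, d2 in _internal_exons(ij):
                    if a1 != a2 or d1 != d2:
                        continue
                    if (b1, c1) == (b2, c2) or _overlap((b1, c1), (b2, c2)):
                        continue
                    # order internal exons genomically left, right
                    (bl, cl), (br, cr) = sorted([(b1, c1), (b2, c2)])
                    a, d = a1, d1

                    def uses(ix, a=a, b=bl, c=cl, d=d):
                        return (
                            (b, c) in ix["exon_set"]
                            and (a, b) in set(ix["junctions"])
                            and (c, d) in set(ix["junctions"])
                        )

                    def uses_r(ix, a=a, b=br, c=cr, d=d):
                        return (
                            (b, c) in ix["exon_set"]
                            and (a, b) in set(ix["junctions"])
                            and (c, d) in set(ix["junctions"])
                        )

                    inc, exc = (uses, uses_r) if strand == "+" else (uses_r, uses)
                    add(
                        "MX",
                        (a, bl, cl, br, cr, d),
                        f"{a}-{bl}:{cl}-{d}:{a}-{br}:{cr}-{d}",
                        inc,
                        exc,
                    )

            # AF: distinct non-overlapping first exons into a shared exon
            f1 = _first_exon(ii, strand)
            f2 = _first_exon(ij, strand)
            if f1 and f2:
                (ex1, sh1), (ex2, sh2) = f1, f2
                if sh1 == sh2 and ex1 != ex2 and not _overlap(ex1, ex2):
                    exd, exp = sorted((ex1, ex2))  # distal/proximal in genome coords
                    if strand == "-":
                        exd, exp = exp, exd  # distal = further from shared exon
                    add(
                        "AF",
                        (exd, exp, sh1),
                        f"{exd[0]}-{exd[1]}:{exp[0]}-{exp[1]}:{sh1}",
                        lambda ix, ex=exd, sh=sh1, st=strand: _first_exon(ix, st)
                        == (ex, sh),
                        lambda ix, ex=exp, sh=sh1, st=strand: _first_exon(ix, st)
                        == (ex, sh),
                    )

            # AL: distinct non-overlapping last exons out of a shared exon
            l1 = _last_exon(ii, strand)
            l2 = _last_exon(ij, strand)
            if l1 and l2:
                (ex1, sh1), (ex2, sh2) = l1, l2
                if sh1 == sh2 and ex1 != ex2 and not _overlap(ex1, ex2):
                    exp, exd = sorted((ex1, ex2))
                    if strand == "-":
                        exp, exd = exd, exp
                    add(
                        "AL",
                        (exd, exp, sh1),
                        f"{exd[0]}-{exd[1]}:{exp[0]}-{exp[1]}:{sh1}",
                        lambda ix, ex=exd, sh=sh1, st=strand: _last_exon(ix, st)
                        == (ex, sh),
                        lambda ix, ex=exp, sh=sh1, st=strand: _last_exon(ix, st)
                        == (ex, sh),
                    )

    events = []
    for (etype, _key), (coords, member_inc, member_exc) in sorted(
        sigs.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        inc = frozenset(t for t in tids if member_inc(idx[t]))
        exc = frozenset(t for t in tids if member_exc(idx[t]))
        if not inc or not exc:
            continue
        total = inc | exc
        if inc >= total:
            continue
        events.append(
            LocalEvent(
                event_id=f"{gid};{etype}:{chrom}:{coords}:{strand}",
                event_type=etype,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                inclusion_transcripts=inc,
                total_transcripts=total,
            )
        )
    return events


def extract_events(annotation: TranscriptAnnotation) -> list[LocalEvent]:
    """Enumerate all local AS events of an annotation.

    Genes are processed independently; genes with fewer than two
    transcripts yield no events. The result is deterministic and invariant
    to transcript enumeration order.
    """
    out: list[LocalEvent] = []
    for gid in sorted(annotation.genes):
        out.extend(_gene_events(annotation.genes[gid]))
    return out
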