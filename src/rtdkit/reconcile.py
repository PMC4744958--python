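"""Gene-model span reconciliation between two annotation sources.

Before transcript-level deduplication, the declared gene spans of a
reference source (e.g. a curated genome annotation) and an alternative
source (e.g. a splicing-discovery assembly) are compared gene by gene and a
single span is resolved per gene: containment keeps the larger span, partial
overlap keeps the reference span. Transcripts of both sources always survive
into deduplication — only the coordinate record is resolved here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .errors import ConflictError
from .model import AnnotationSet, GeneModel, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)


class Resolution(str, Enum):
    REF_ONLY = "ref_only"
    ALT_ONLY = "alt_only"
    IDENTICAL = "identical"
    CONTAINMENT_KEEP_LARGER = "containment_keep_larger"
    PARTIAL_OVERLAP_KEEP_REF = "partial_overlap_keep_ref"
    #: same gene_id, non-overlapping spans: keep the reference span, warn
    DISJOINT_KEEP_REF = "disjoint_keep_ref"


@dataclass(frozen=True)
class GenePairing:
    gene_id: str
    span_ref: GenomicInterval | None
    span_alt: GenomicInterval | None
    resolution: Resolution


def _classify(ref: GenomicInterval, alt: GenomicInterval) -> Resolution:
    if ref.start == alt.start and ref.end == alt.end:
        return Resolution.IDENTICAL
    if ref.contains(alt) or alt.contains(ref):
        return Resolution.CONTAINMENT_KEEP_LARGER
    if ref.overlaps(alt):
        return Resolution.PARTIAL_OVERLAP_KEEP_REF
    return Resolution.DISJOINT_KEEP_REF


def pair_genes(ref: AnnotationSet, alt: AnnotationSet) -> list[GenePairing]:
    """One pairing per gene_id in the union of the two sources."""
    conflicts = []
    pairings = []
    for gid in sorted(set(ref.genes) | set(alt.genes)):
        rg = ref.genes.get(gid)
        ag = alt.genes.get(gid)
        if rg is not None and ag is not None and rg.span.chrom != ag.span.chrom:
            conflicts.append(gid)
            continue
        if rg is None:
            res = Resolution.ALT_ONLY
        elif ag is None:
            res = Resolution.REF_ONLY
        else:
            res = _classify(rg.span, ag.span)
        pairings.append(
            GenePairing(
                gid,
                rg.span if rg else None,
                ag.span if ag else None,
                res,
            )
        )
    if conflicts:
        raise ConflictError(
            "gene(s) on different chromosomes in the two sources: "
            + ", ".join(conflicts)
        )
    return pairings


def resolve_span(p: GenePairing) -> GenomicInterval:
    """The single span a pairing resolves to.

    Containment (including equality) keeps the larger span, with the
    reference winning ties; partial overlap and disjoint spans keep the
    reference span (disjoint with a warning, since the sources then disagree
    outright about where the gene is).
    """
    if p.span_ref is None:
        assert p.span_alt is not None
        return p.span_alt
    if p.span_alt is None:
        return p.span_ref
    res = p.resolution
    if res in (Resolution.IDENTICAL, Resolution.REF_ONLY):
        return p.span_ref
    if res is Resolution.CONTAINMENT_KEEP_LARGER:
        # equality resolves to the reference span (identical coordinates anyway)
        return p.span_alt if p.span_alt.length > p.span_ref.length else p.span_ref
    if res is Resolution.DISJOINT_KEEP_REF:
        logger.warning(
            "gene %s: disjoint spans %s vs %s; keeping reference",
            p.gene_id,
            (p.span_ref.start, p.span_ref.end),
            (p.span_alt.start, p.span_alt.end),
        )
    return p.span_ref


def apply_resolutions(
    ref: AnnotationSet,
    alt: AnnotationSet,
    pairings: list[GenePairing],
    source_label: str = "merged",
) -> AnnotationSet:
    """Materialize the merged, pre-dedup union of two sources.

    Every transcript of both sources is retained, grouped under one gene
    model per gene_id with the resolved span. An alternative-source
    transcript whose id and exon structure both match a reference transcript
    is the same transcript and enters once; an id collision with different
    structure is disambiguated by suffixing the alternative source's label.
    A transcript extending outside the resolved span widens it, with a
    warning.
    """
    by_gene = {p.gene_id: p for p in pairings}
    missing = (set(ref.genes) | set(alt.genes)) - set(by_gene)
    if missing:
        raise ValueError(f"pairings do not cover genes: {sorted(missing)}")

    ref_txs = {t.transcript_id: t for t in ref.transcripts()}
    genes: dict[str, GeneModel] = {}
    for gid, p in sorted(by_gene.items()):
        txs: list[TranscriptModel] = []
        if gid in ref.genes:
            txs.extend(ref.genes[gid].transcripts)
        if gid in alt.genes:
            for t in alt.genes[gid].transcripts:
                prev = ref_txs.get(t.transcript_id)
                if prev is not None:
                    if prev.exons == t.exons:
                        continue  # same transcript present in both sources
                    new_id = f"{t.transcript_id}_{alt.source_label or 'alt'}"
                    logger.info(
                        "transcript id collision: %s renamed to %s",
                        t.transcript_id,
                        new_id,
                    )
                    t = TranscriptModel(new_id, t.gene_id, t.exons, source=t.source)
                txs.append(t)
        if not txs:
            continue
        span = resolve_span(p)
        lo = min(min(t.span.start for t in txs), span.start)
        hi = max(max(t.span.end for t in txs), span.end)
        if (lo, hi) != (span.start, span.end):
            logger.warning(
                "gene %s: transcripts extend outside resolved span; widening "
                "%d-%d to %d-%d",
                gid,
                span.start,
                span.end,
                lo,
                hi,
            )
            span = GenomicInterval(span.chrom, lo, hi, span.strand)
        genes[gid] = GeneModel(gid, tuple(txs), span=span)
    return AnnotationSet(genes=genes, source_label=source_label)


def write_pairing_report(pairings: list[GenePairing], path) -> None:
    """TSV report: gene_id, ref_span, alt_span, resolution."""
    with open(path, "w") as fh:
        fh.write("gene_id\tref_span\talt_span\tresolution\n")
        for p in pairings:
            fh.write(
                "\t".join(
                    [
                        p.gene_id,
                        _fmt(p.span_ref),
                        _fmt(p.span_alt),
                        p.resolution.value,
                    ]
                )
                + "\n"
            )


def _fmt(iv: GenomicInterval | None) -> str:
    return "." if iv is None else f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"
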