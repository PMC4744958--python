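"""Core domain types: genomic intervals, transcript and gene models, annotation sets.

Coordinates are 1-based and inclusive throughout (the GFF3 convention shared
by both annotation dialects we read); any half-open arithmetic is internal to
individual functions and never surfaces in these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import ValidationError

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval [start, end] on one strand of one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies within this interval (same chrom; strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class IntronChain:
    """The ordered intron coordinates of a transcript — the deduplication key.

    Two spliced transcripts with identical chains have identical internal
    structure and can differ only in the lengths of their terminal (UTR)
    exons. Mono-exon transcripts have an empty chain.
    """

    chrom: str
    strand: str
    introns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.introns:
            if start <= prev_end or end < start:
                raise ValidationError(
                    f"introns must be ascending and disjoint, got {self.introns}"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.introns)

    @property
    def is_empty(self) -> bool:
        return not self.introns


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered run of exons on a single chromosome strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} spans multiple "
                f"chromosomes/strands: {chroms} {strands}"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end + 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons {a.start}-{a.end} and "
                    f"{b.start}-{b.end} overlap or are adjacent (need a >=1 bp gap)"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        """Total exonic length in bp — the mature transcript length."""
        return sum(e.length for e in self.exons)

    def intron_chain(self) -> IntronChain:
        introns = tuple(
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        )
        return IntronChain(self.chrom, self.strand, introns)


@dataclass(frozen=True)
class GeneModel:
    """A gene: its declared span and the transcripts assigned to it.

    The span may be wider than the union of transcript spans (a source may
    declare gene boundaries beyond observed transcripts) but must cover it.
    """

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    span: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")
        txs = tuple(sorted(self.transcripts, key=lambda t: t.transcript_id))
        object.__setattr__(self, "transcripts", txs)
        for t in txs:
            if t.gene_id != self.gene_id:
                raise ValidationError(
                    f"transcript {t.transcript_id} has gene_id {t.gene_id}, "
                    f"expected {self.gene_id}"
                )
        union = self.transcript_union()
        if self.span is None:
            object.__setattr__(self, "span", union)
        elif not self.span.contains(union):
            raise ValidationError(
                f"gene {self.gene_id}: declared span "
                f"{self.span.start}-{self.span.end} does not cover transcripts "
                f"({union.start}-{union.end})"
            )

    def transcript_union(self) -> GenomicInterval:
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValidationError(
                f"gene {self.gene_id} has transcripts on several chromosomes"
            )
        return GenomicInterval(
            self.transcripts[0].chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
            self.transcripts[0].strand,
        )

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    def get(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass
class AnnotationSet:
    """A collection of gene models from one source (or a merged dataset).

    ``source_label`` names the provenance and is excluded from equality:
    two sets are equal when they describe the same gene models.
    """

    genes: dict[str, GeneModel] = field(default_factory=dict)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for gid, gene in self.genes.items():
            if gene.gene_id != gid:
                raise ValidationError(f"gene key {gid} != gene_id {gene.gene_id}")
            for t in gene.transcripts:
                if t.transcript_id in seen:
                    raise ValidationError(
                        f"duplicate transcript_id {t.transcript_id} "
                        f"(genes {seen[t.transcript_id]} and {gid})"
                    )
                seen[t.transcript_id] = gid

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.genes == other.genes

    @classmethod
    def from_transcripts(
        cls,
        transcripts: list[TranscriptModel],
        source_label: str = "",
        gene_spans: dict[str, GenomicInterval] | None = None,
    ) -> "AnnotationSet":
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        spans = gene_spans or {}
        genes = {
            gid: GeneModel(gid, tuple(ts), span=spans.get(gid))
            for gid, ts in by_gene.items()
        }
        return cls(genes=genes, source_label=source_label)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gid in sorted(self.genes):
            yield from self.genes[gid].transcripts

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(g.n_transcripts for g in self.genes.values())

    def transcript_ids(self) -> set[str]:
        return {t.transcript_id for t in self.transcripts()}

    def get_transcript(self, transcript_id: str) -> TranscriptModel:
        for gene in self.genes.values():
            for t in gene.transcripts:
                if t.transcript_id == transcript_id:
                    return t
        raise KeyError(transcript_id)
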