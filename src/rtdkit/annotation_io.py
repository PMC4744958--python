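"""Reading and writing transcript annotations (GTF / GFF3) and transcript FASTA.

Both dialects are read natively into the same :class:`AnnotationSet`, so no
external format conversion step is needed. Only gene / transcript / exon
features contribute to the model; everything else (CDS, UTR, chromosome
lines, ...) is counted and skipped — deduplication operates on intron
coordinates, for which exons suffice.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pyfaidx
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

from .errors import CoordinateError, ParseError, ValidationError
from .model import AnnotationSet, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

TRANSCRIPT_TYPES = {"mRNA", "transcript"}
#: feature types consumed when building models; everything else is skipped
MODEL_TYPES = {"gene", "exon"} | TRANSCRIPT_TYPES


def detect_dialect(path: str | Path) -> str:
    """Guess the annotation dialect from the first feature line.

    GTF attribute columns look like ``key "value";`` while GFF3 uses
    ``key=value``. Files with no feature lines default to GFF3.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                continue
            attrs = cols[8]
            if "=" in attrs.split(";")[0] and '"' not in attrs.split(";")[0]:
                return "gff3"
            return "gtf"
    return "gff3"


def read_annotation(
    path: str | Path,
    dialect: str | None = None,
    source_label: str | None = None,
) -> AnnotationSet:
    """Parse a GTF or GFF3 file into an :class:`AnnotationSet`.

    Transcript and gene identity come from ``transcript_id``/``gene_id``
    attributes (GTF) or ``ID``/``Parent`` links (GFF3). Exons that arrive
    unsorted are sorted with a warning. Declared gene-feature spans are kept
    when present (they may exceed the union of transcript spans).
    """
    path = Path(path)
    if dialect is None:
        dialect = detect_dialect(path)
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if source_label is None:
        source_label = path.stem

    # transcript_id -> (gene_id, source, [exon intervals])
    tx_exons: dict[str, tuple[str, str, list[GenomicInterval]]] = {}
    tx_parent: dict[str, str] = {}  # GFF3: mRNA ID -> gene ID
    gene_spans: dict[str, GenomicInterval] = {}
    tx_order: list[str] = []
    n_ignored = 0

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, got {len(cols)}", lineno
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare ValueError
                raise ParseError(f"cannot parse feature: {exc}", lineno) from exc
            ftype = feat.featuretype
            if ftype not in MODEL_TYPES:
                n_ignored += 1
                continue
            if feat.start is None or feat.end is None:
                raise ParseError("missing coordinates", lineno)
            if feat.start > feat.end:
                raise ValidationError(
                    f"line {lineno}: {ftype} has start {feat.start} > end {feat.end}"
                )
            if feat.strand not in ("+", "-"):
                raise ParseError(f"unsupported strand {feat.strand!r}", lineno)

            attrs = feat.attributes
            if ftype == "gene":
                gid = _first(attrs, "ID" if dialect == "gff3" else "gene_id", lineno)
                gene_spans[gid] = GenomicInterval(
                    feat.seqid, feat.start, feat.end, feat.strand
                )
            elif ftype in TRANSCRIPT_TYPES:
                if dialect == "gff3":
                    tid = _first(attrs, "ID", lineno)
                    tx_parent[tid] = _first(attrs, "Parent", lineno)
                # GTF transcript lines carry nothing the exon lines do not
            else:  # exon
                if dialect == "gtf":
                    tid = _first(attrs, "transcript_id", lineno)
                    gid = _first(attrs, "gene_id", lineno)
                else:
                    tid = _first(attrs, "Parent", lineno)
                    gid = tx_parent.get(tid, "")
                if tid not in tx_exons:
                    tx_exons[tid] = (gid, feat.source or "", [])
                    tx_order.append(tid)
                tx_exons[tid][2].append(
                    GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
                )

    if n_ignored:
        logger.info("%s: ignored %d non-model feature lines", path, n_ignored)

    transcripts = []
    for tid in tx_order:
        gid, src, exons = tx_exons[tid]
        if not gid:
            # GFF3 exon whose parent transcript feature was absent
            gid = tx_parent.get(tid, tid)
        starts = [e.start for e in exons]
        if starts != sorted(starts):
            logger.warning("transcript %s: exons unsorted in file, sorting", tid)
        transcripts.append(
            TranscriptModel(tid, gid, tuple(exons), source=src or source_label)
        )
    return AnnotationSet.from_transcripts(
        transcripts, source_label=source_label, gene_spans=gene_spans
    )


def _first(attrs, key: str, lineno: int) -> str:
    vals = attrs.get(key, [])
    if not vals:
        raise ParseError(f"missing required attribute {key!r}", lineno)
    return vals[0]


def write_annotation(aset: AnnotationSet, path: str | Path, dialect: str = "gff3") -> None:
    """Write an :class:`AnnotationSet` as GTF or GFF3.

    Output is normalized: genes sorted by (chrom, start, gene_id), exons in
    ascending coordinate order, so write(read(f)) is a fixed point.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes = sorted(
        aset.genes.values(), key=lambda g: (g.span.chrom, g.span.start, g.gene_id)
    )
    lines = ["##gff-version 3"] if dialect == "gff3" else ["#!rtdkit gtf"]
    for gene in genes:
        s = gene.span
        # gene lines use a fixed source so output is a normalization fixed point
        src = "rtdkit"
        if dialect == "gff3":
            lines.append(_row(s, src, "gene", f"ID={gene.gene_id}"))
        else:
            lines.append(_row(s, src, "gene", f'gene_id "{gene.gene_id}";'))
        for t in sorted(gene.transcripts, key=lambda t: (t.span.start, t.transcript_id)):
            tsrc = t.source or src
            ts = t.span
            if dialect == "gff3":
                lines.append(
                    _row(ts, tsrc, "mRNA", f"ID={t.transcript_id};Parent={t.gene_id}")
                )
                exon_attr = f"Parent={t.transcript_id}"
            else:
                lines.append(
                    _row(
                        ts,
                        tsrc,
                        "transcript",
                        f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";',
                    )
                )
                exon_attr = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                )
            for e in t.exons:
                lines.append(_row(e, tsrc, "exon", exon_attr))
    Path(path).write_text("\n".join(lines) + "\n")


def _row(iv: GenomicInterval, source: str, ftype: str, attrs: str) -> str:
    return "\t".join(
        [iv.chrom, source, ftype, str(iv.start), str(iv.end), ".", iv.strand, ".", attrs]
    )


def extract_transcript_sequences(
    aset: AnnotationSet, genome: str | Path
) -> dict[str, str]:
    """Extract spliced transcript sequences from a genome FASTA.

    Exon subsequences are concatenated in ascending coordinate order and the
    whole sequence is reverse-complemented for minus-strand transcripts, so
    every returned sequence reads 5'->3'.
    """
    fa = pyfaidx.Fasta(str(genome))
    out: dict[str, str] = {}
    for t in aset.transcripts():
        if t.chrom not in fa:
            raise KeyError(f"chromosome {t.chrom!r} not in genome FASTA")
        chrom_len = len(fa[t.chrom])
        if t.span.end > chrom_len:
            raise CoordinateError(
                f"transcript {t.transcript_id} ends at {t.span.end} beyond "
                f"{t.chrom} length {chrom_len}"
            )
        seq = "".join(str(fa[t.chrom][e.start - 1 : e.end]) for e in t.exons)
        if t.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[t.transcript_id] = seq
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
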