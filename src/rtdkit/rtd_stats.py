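"""Summary statistics of a transcript dataset.

Covers the headline numbers used to characterize a reference transcript
dataset: gene and transcript counts, the average number of transcripts per
gene, the transcripts-per-gene histogram, and the fraction of
intron-containing genes with more than one transcript — the working
estimate of how many spliced genes undergo alternative splicing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import ValidationError
from .model import AnnotationSet


def _round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (presentation convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RtdSummary:
    n_genes: int
    n_transcripts: int
    avg_transcripts_per_gene: float | None
    histogram: dict[int, int]
    n_intron_genes: int
    n_intron_genes_multi: int
    as_percent: float | None

    def to_dict(self) -> dict:
        d = {
            "n_genes": self.n_genes,
            "n_transcripts": self.n_transcripts,
            "avg_transcripts_per_gene": self.avg_transcripts_per_gene,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "n_intron_genes": self.n_intron_genes,
            "n_intron_genes_multi": self.n_intron_genes_multi,
            "as_percent": self.as_percent,
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def avg_transcripts_per_gene(n_genes: int, n_transcripts: int) -> float:
    """Mean transcripts per gene, reported at 2 decimals."""
    if n_genes <= 0:
        raise ValidationError("average transcripts per gene undefined for 0 genes")
    return _round2(n_transcripts / n_genes)


def summarize(aset: AnnotationSet) -> RtdSummary:
    """Dataset summary.

    An intron-containing gene is one with at least one transcript having at
    least one intron; the alternative-splicing percentage is the share of
    those genes carrying more than one transcript. Both quantities are
    ``None``/absent when their denominator is zero.
    """
    histogram: dict[int, int] = {}
    n_intron = 0
    n_intron_multi = 0
    n_tx = 0
    for gene in aset.genes.values():
        k = gene.n_transcripts
        n_tx += k
        histogram[k] = histogram.get(k, 0) + 1
        if any(t.n_exons > 1 for t in gene.transcripts):
            n_intron += 1
            if k > 1:
                n_intron_multi += 1
    n_genes = aset.n_genes
    return RtdSummary(
        n_genes=n_genes,
        n_transcripts=n_tx,
        avg_transcripts_per_gene=(
            avg_transcripts_per_gene(n_genes, n_tx) if n_genes else None
        ),
        histogram=histogram,
        n_intron_genes=n_intron,
        n_intron_genes_multi=n_intron_multi,
        as_percent=(_round2(100 * n_intron_multi / n_intron) if n_intron else None),
    )


def write_histogram(summary: RtdSummary, path) -> None:
    """TSV of the transcripts-per-gene distribution."""
    with open(path, "w") as fh:
        fh.write("transcripts_per_gene\tn_genes\n")
        for k in sorted(summary.histogram):
            fh.write(f"{k}\t{summary.histogram[k]}\n")
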