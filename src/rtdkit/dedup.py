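"""Redundancy removal: the computational core of reference-transcript-dataset construction.

Three rules, applied per gene in a fixed order after span reconciliation:

1. ``same_chain_shorter_utr`` — spliced transcripts sharing an identical
   intron chain differ only in UTR length; the one with the greatest spliced
   length is retained.
2. ``monoexon_shorter`` — overlapping mono-exon transcripts of a gene are
   UTR variants of each other; only the longest is retained
   (non-overlapping mono-exon transcripts are genuinely distinct and kept).
3. ``fragment`` — an incomplete transcript model (typically from low read
   coverage) whose intron chain is consistent with a longer transcript's is
   removed. The predicate is written so that genuine intron-retention
   isoforms — which share a *subset* of a longer transcript's introns but
   cover the retained intron with an exon — are never treated as fragments.

Curated transcripts (added after automated construction) are exempt from
removal but still knock out non-curated duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable

from .errors import ConflictError
from .model import AnnotationSet, GeneModel, TranscriptModel
from .reconcile import apply_resolutions, pair_genes

logger = logging.getLogger(__name__)


class Rule(str, Enum):
    SAME_CHAIN_SHORTER_UTR = "same_chain_shorter_utr"
    MONOEXON_SHORTER = "monoexon_shorter"
    FRAGMENT = "fragment"


@dataclass(frozen=True)
class DedupDecision:
    """Audit-trail record of one removal."""

    removed_transcript_id: str
    kept_transcript_id: str
    rule: Rule
    gene_id: str


@dataclass
class DedupConfig:
    """Knobs for deterministic tie-breaking and curation.

    ref_label: source tag preferred when spliced lengths tie.
    curated_labels: source tags whose transcripts are exempt from removal.
    """

    ref_label: str = ""
    curated_labels: frozenset[str] = frozenset()
    merged_label: str = "rtd"

    def is_protected(self, t: TranscriptModel) -> bool:
        return t.source in self.curated_labels


def _pref_key(t: TranscriptModel, cfg: DedupConfig):
    """Sort key: longest spliced length first, then reference source, then id."""
    return (-t.spliced_length, 0 if t.source == cfg.ref_label else 1, t.transcript_id)


def intron_chain(t: TranscriptModel):
    """The transcript's ordered intron coordinates (empty for mono-exon)."""
    return t.intron_chain()


def collapse_identical_chains(
    g: GeneModel, cfg: DedupConfig | None = None
) -> tuple[GeneModel, list[DedupDecision]]:
    """Keep one transcript per distinct nonempty intron chain: the longest.

    Transcripts with identical chains have identical internal structure, so
    any length difference is UTR sequence; the maximal spliced length
    (not genomic span) picks the survivor. Mono-exon transcripts are
    untouched here.
    """
    cfg = cfg or DedupConfig()
    groups: dict[tuple, list[TranscriptModel]] = {}
    kept: list[TranscriptModel] = []
    for t in g.transcripts:
        chain = t.intron_chain()
        if chain.is_empty:
            kept.append(t)
        else:
            groups.setdefault((chain.chrom, chain.strand, chain.introns), []).append(t)

    decisions: list[DedupDecision] = []
    for members in groups.values():
        members.sort(key=lambda t: _pref_key(t, cfg))
        protected = [t for t in members if cfg.is_protected(t)]
        if protected:
            survivors = protected
            keeper = protected[0]
        else:
            survivors = [members[0]]
            keeper = members[0]
        surviving_ids = {t.transcript_id for t in survivors}
        kept.extend(survivors)
        for t in members:
            if t.transcript_id not in surviving_ids:
                decisions.append(
                    DedupDecision(
                        t.transcript_id,
                        keeper.transcript_id,
                        Rule.SAME_CHAIN_SHORTER_UTR,
                        g.gene_id,
                    )
                )
    return GeneModel(g.gene_id, tuple(kept), span=g.span), decisions


def collapse_monoexon(
    g: GeneModel, cfg: DedupConfig | None = None
) -> tuple[GeneModel, list[DedupDecision]]:
    """Among overlapping same-strand mono-exon transcripts, keep the longest.

    Processed in descending length order: a transcript is removed iff it
    overlaps an already-retained strictly longer mono-exon transcript (or an
    equal-length one with an identical span). Non-overlapping mono-exon
    transcripts of the same gene are all retained.
    """
    cfg = cfg or DedupConfig()
    mono = [t for t in g.transcripts if t.n_exons == 1]
    other = [t for t in g.transcripts if t.n_exons > 1]
    mono.sort(key=lambda t: _pref_key(t, cfg))
    retained: list[TranscriptModel] = []
    decisions: list[DedupDecision] = []
    for t in mono:
        remover = None
        if not cfg.is_protected(t):
            for u in retained:
                if u.strand != t.strand or not u.span.overlaps(t.span):
                    continue
                if u.spliced_length > t.spliced_length or (
                    u.spliced_length == t.spliced_length and u.span == t.span
                ):
                    remover = u
                    break
        if remover is None:
            retained.append(t)
        else:
            decisions.append(
                DedupDecision(
                    t.transcript_id,
                    remover.transcript_id,
                    Rule.MONOEXON_SHORTER,
                    g.gene_id,
                )
            )
    return GeneModel(g.gene_id, tuple(other + retained), span=g.span), decisions


def is_fragment(short: TranscriptModel, long: TranscriptModel) -> bool:
    """True iff ``short`` is an incomplete model of ``long``.

    Requires (a) short's span strictly inside long's span at one end at
    least, (b) every intron of short present in long's chain, and (c) every
    intron of long lying strictly within short's span present in short's
    chain. Condition (c) is what saves intron-retention isoforms: a retained
    intron of ``long`` inside ``short``'s span that ``short`` does not
    splice marks ``short`` as a genuine isoform, not a fragment.
    """
    if short.gene_id != long.gene_id:
        raise ValueError("fragment test requires transcripts of the same gene")
    if short.chrom != long.chrom or short.strand != long.strand:
        raise ValueError("fragment test requires the same chromosome and strand")
    if short.spliced_length >= long.spliced_length:
        raise ValueError("fragment test requires short strictly shorter than long")
    ss, ls = short.span, long.span
    if not ls.contains(ss):
        return False
    if ss.start == ls.start and ss.end == ls.end:
        return False  # span-identical transcripts are isoforms, never fragments
    short_introns = set(short.intron_chain().introns)
    long_introns = long.intron_chain().introns
    if not short_introns <= set(long_introns):
        return False
    for intron in long_introns:
        if intron[0] > ss.start and intron[1] < ss.end:
            if intron not in short_introns:
                return False
    return True


def remove_fragments(
    g: GeneModel, cfg: DedupConfig | None = None
) -> tuple[GeneModel, list[DedupDecision]]:
    """Drop every transcript that is a fragment of a retained longer one.

    Transcripts are processed in descending spliced-length order so a
    fragment, once removed, can never shield another fragment; the decision
    names the longest retained transcript the fragment matched.
    """
    cfg = cfg or DedupConfig()
    ordered = sorted(g.transcripts, key=lambda t: _pref_key(t, cfg))
    retained: list[TranscriptModel] = []
    decisions: list[DedupDecision] = []
    for t in ordered:
        keeper = None
        if not cfg.is_protected(t):
            for u in retained:  # retained is length-descending: first hit is longest
                if u.spliced_length > t.spliced_length and is_fragment(t, u):
                    keeper = u
                    break
        if keeper is None:
            retained.append(t)
        else:
            decisions.append(
                DedupDecision(
                    t.transcript_id, keeper.transcript_id, Rule.FRAGMENT, g.gene_id
                )
            )
    return GeneModel(g.gene_id, tuple(retained), span=g.span), decisions


def dedup_gene(
    g: GeneModel, cfg: DedupConfig | None = None
) -> tuple[GeneModel, list[DedupDecision]]:
    """Apply the three rules in their fixed order to one gene."""
    cfg = cfg or DedupConfig()
    decisions: list[DedupDecision] = []
    for step in (collapse_identical_chains, collapse_monoexon, remove_fragments):
        g, d = step(g, cfg)
        decisions.extend(d)
    return g, decisions


def merge_curated(
    aset: AnnotationSet, curated: AnnotationSet, cfg: DedupConfig | None = None
) -> tuple[AnnotationSet, list[DedupDecision]]:
    """Add manually curated transcripts, exempt from removal.

    Curated transcripts can still displace non-curated duplicates (e.g. a
    same-chain shorter automated model), so the dedup rules are re-applied
    to every gene the curated set touches, with curated transcripts
    protected. A curated transcript id colliding with an existing id of
    different structure is a conflict.
    """
    cfg = cfg or DedupConfig()
    cfg = replace(
        cfg, curated_labels=cfg.curated_labels | {curated.source_label or "curated"}
    )
    existing = {t.transcript_id: t for t in aset.transcripts()}
    genes = dict(aset.genes)
    decisions: list[DedupDecision] = []
    for gid in sorted(curated.genes):
        cg = curated.genes[gid]
        new_txs: list[TranscriptModel] = []
        for t in cg.transcripts:
            if t.source not in cfg.curated_labels:
                t = TranscriptModel(
                    t.transcript_id,
                    t.gene_id,
                    t.exons,
                    source=curated.source_label or "curated",
                )
            prev = existing.get(t.transcript_id)
            if prev is not None:
                if prev.exons == t.exons:
                    continue  # same structure already present under this id
                raise ConflictError(
                    f"curated transcript {t.transcript_id} collides with an "
                    "existing transcript of different structure"
                )
            new_txs.append(t)
        if not new_txs:
            continue
        if gid in genes:
            old = genes[gid]
            span = old.span
            lo = min(span.start, min(t.span.start for t in new_txs))
            hi = max(span.end, max(t.span.end for t in new_txs))
            if (lo, hi) != (span.start, span.end):
                span = replace(span, start=lo, end=hi)
            merged = GeneModel(gid, old.transcripts + tuple(new_txs), span=span)
        else:
            merged = GeneModel(gid, tuple(new_txs), span=cg.span)
        merged, d = dedup_gene(merged, cfg)
        decisions.extend(d)
        genes[gid] = merged
    return AnnotationSet(genes=genes, source_label=aset.source_label), decisions


def build_rtd(
    ref: AnnotationSet,
    alt: AnnotationSet,
    curated: AnnotationSet | None = None,
    cfg: DedupConfig | None = None,
) -> tuple[AnnotationSet, list[DedupDecision]]:
    """Full construction pipeline for a nonredundant reference transcript dataset.

    Stage order: span reconciliation, then per gene identical-chain
    collapse, mono-exon collapse and fragment removal, then the curated
    merge. The output is nonredundant: running the pipeline on it again
    yields zero decisions.
    """
    if cfg is None:
        cfg = DedupConfig(ref_label=ref.source_label)
    pairings = pair_genes(ref, alt)
    merged = apply_resolutions(ref, alt, pairings, source_label=cfg.merged_label)
    genes = {}
    decisions: list[DedupDecision] = []
    for gid in sorted(merged.genes):
        g, d = dedup_gene(merged.genes[gid], cfg)
        genes[gid] = g
        decisions.extend(d)
    out = AnnotationSet(genes=genes, source_label=cfg.merged_label)
    if curated is not None and curated.n_genes:
        out, d = merge_curated(out, curated, cfg)
        decisions.extend(d)
    return out, decisions


def write_decision_ledger(decisions: Iterable[DedupDecision], path) -> None:
    """TSV audit trail: removed_id, kept_id, rule, gene_id."""
    with open(path, "w") as fh:
        fh.write("removed_id\tkept_id\trule\tgene_id\n")
        for d in decisions:
            fh.write(
                f"{d.removed_transcript_id}\t{d.kept_transcript_id}\t"
                f"{d.rule.value}\t{d.gene_id}\n"
            )
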