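"""Deterministic synthetic data: genomes, redundant annotation pairs with
known ground truth, and paired abundance / RT-PCR peak tables.

The generator emulates the situation a reference-transcript-dataset build
faces: a curated reference annotation and a splicing-discovery annotation
share gene identifiers but disagree on gene spans and contain three kinds
of redundant transcript (same-chain UTR variants, mono-exon UTR variants,
coverage fragments). Every injected redundant transcript is recorded in a
truth ledger together with the rule that must remove it, and genuine
alternative-splicing isoforms — including intron-retention isoforms, which
a naive fragment rule would destroy — are built so that exactly the true
transcripts survive construction.

The paired measurement design mirrors a two-method validation experiment:
three biological replicates at two time-points, transcript abundances (TPM)
and event-level peak areas (RFU) derived from the same latent per-replicate
abundances, with multiplicative log-normal noise on the peak areas
controlling how well the two methods can agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dedup import Rule
from .errors import ValidationError
from .model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from .splice_ratio import AbundanceTable, ASEvent, PeakTable, RatioRecord, SampleInfo

CHROM = "Chr1"
REF_LABEL = "reference"
ALT_LABEL = "discovery"


@dataclass(frozen=True)
class RedundancyRates:
    """Per-gene injection probabilities for each redundancy class."""

    utr_variant: float = 0.5
    monoexon_variant: float = 0.5
    fragment: float = 0.5
    contained_gene_model: float = 0.3
    partial_overlap_gene_model: float = 0.3

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"rate {name}={v} outside [0, 1]")

    @classmethod
    def uniform(cls, rate: float) -> "RedundancyRates":
        return cls(rate, rate, rate, rate, rate)


@dataclass(frozen=True)
class FixtureSpec:
    """Study-design parameters of the synthetic world.

    Defaults emulate a merge of a curated and a discovery annotation:
    mostly multi-exon genes, on average ~2 isoforms per spliced gene, a
    substantial fraction of genes carrying redundant models, and moderate
    measurement noise on the RT-PCR side.
    """

    seed: int = 1
    n_genes: int = 50
    p_monoexon_gene: float = 0.15
    p_alt_only_gene: float = 0.1
    mean_extra_isoforms: float = 1.2
    max_extra_isoforms: int = 3
    redundancy_rates: RedundancyRates = field(default_factory=RedundancyRates)
    noise_sd: float = 0.25
    bio_sd: float = 0.15
    flank: int = 25
    time_points: tuple[str, ...] = ("T1", "T2")
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.noise_sd < 0 or self.bio_sd < 0:
            raise ValidationError("noise scales must be non-negative")


@dataclass(frozen=True)
class TruthEntry:
    """One injected redundant transcript and the rule that must remove it."""

    removed_id: str
    rule: Rule
    kept_id: str
    gene_id: str


@dataclass
class _Edit:
    """One true AS isoform: its type and the genomic window it alters."""

    transcript_id: str
    event_type: str  # IR | Alt5 | Alt3 | ES
    window: tuple[int, int]


@dataclass
class World:
    """Everything one seed generates, with shared ground truth."""

    spec: FixtureSpec
    chrom_len: int
    ref: AnnotationSet
    alt: AnnotationSet
    truth: AnnotationSet
    truth_ledger: list[TruthEntry]
    events: list[ASEvent]
    ir_isoform_ids: set[str]


def _exon(start: int, end: int, strand: str) -> GenomicInterval:
    return GenomicInterval(CHROM, start, end, strand)


def _make_isoform(
    base: list[tuple[int, int]], edit_kind: str, idx: int, delta: int
) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Apply one edit to a base exon list; returns (exons, altered window)."""
    introns = [(base[i][1] + 1, base[i + 1][0] - 1) for i in range(len(base) - 1)]
    exons = list(base)
    if edit_kind == "IR":
        s, e = introns[idx]
        merged = (exons[idx][0], exons[idx + 1][1])
        exons = exons[:idx] + [merged] + exons[idx + 2 :]
        return exons, (s, e)
    if edit_kind == "AltL":  # intron start moves right: donor shift on + strand
        s, e = introns[idx]
        exons[idx] = (exons[idx][0], exons[idx][1] + delta)
        return exons, (s, e)
    if edit_kind == "AltR":  # intron end moves left: acceptor shift on + strand
        s, e = introns[idx]
        exons[idx + 1] = (exons[idx + 1][0] - delta, exons[idx + 1][1])
        return exons, (s, e)
    if edit_kind == "ES":  # skip internal exon idx (1-based inside)
        s = introns[idx - 1][0]
        e = introns[idx][1]
        exons = exons[:idx] + exons[idx + 1 :]
        return exons, (s, e)
    raise ValueError(edit_kind)


def _edit_event_type(kind: str, strand: str) -> str:
    if kind == "IR":
        return "IR"
    if kind == "ES":
        return "ES"
    if kind == "AltL":  # left intron boundary = 5'ss on +, 3'ss on -
        return "Alt5" if strand == "+" else "Alt3"
    return "Alt3" if strand == "+" else "Alt5"


def generate_world(spec: FixtureSpec) -> World:
    """Build the full synthetic world for one seed (pure function of spec)."""
    rng = np.random.default_rng([0, spec.seed])
    rates = spec.redundancy_rates

    truth_txs: list[TranscriptModel] = []
    ref_txs: list[TranscriptModel] = []
    alt_txs: list[TranscriptModel] = []
    ledger: list[TruthEntry] = []
    edits_by_gene: dict[str, list[_Edit]] = {}
    gene_strand: dict[str, str] = {}
    ref_spans: dict[str, GenomicInterval] = {}
    alt_spans: dict[str, GenomicInterval] = {}
    truth_spans: dict[str, GenomicInterval] = {}
    ir_ids: set[str] = set()

    cursor = 1001
    for gi in range(spec.n_genes):
        gid = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_strand[gid] = strand
        alt_only = rng.random() < spec.p_alt_only_gene
        mono = rng.random() < spec.p_monoexon_gene

        if mono:
            length = int(rng.integers(300, 1501))
            base = [(cursor, cursor + length - 1)]
        else:
            n_exons = int(rng.integers(2, 7))
            pos = cursor
            base = []
            for k in range(n_exons):
                elen = int(rng.integers(100, 301))
                base.append((pos, pos + elen - 1))
                if k < n_exons - 1:
                    pos = base[-1][1] + 1 + int(rng.integers(80, 251))
        base_tx = TranscriptModel(
            f"{gid}.1",
            gid,
            tuple(_exon(s, e, strand) for s, e in base),
            source=ALT_LABEL if alt_only else REF_LABEL,
        )
        gene_truth = [base_tx]
        edits: list[_Edit] = []

        if not mono:
            # enumerate distinct edit slots; each (kind, intron/exon) used once
            slots = []
            n_introns = len(base) - 1
            for i in range(n_introns):
                slots.extend([("IR", i), ("AltL", i), ("AltR", i)])
            for j in range(1, len(base) - 1):
                slots.append(("ES", j))
            n_extra = min(
                spec.max_extra_isoforms,
                int(rng.poisson(spec.mean_extra_isoforms)),
                len(slots),
            )
            chosen = rng.choice(len(slots), size=n_extra, replace=False)
            for k, si in enumerate(sorted(int(c) for c in chosen), start=2):
                kind, idx = slots[si]
                delta = int(rng.integers(3, 13))
                exons, window = _make_isoform(base, kind, idx, delta)
                tid = f"{gid}.{k}"
                iso = TranscriptModel(
                    tid,
                    gid,
                    tuple(_exon(s, e, strand) for s, e in exons),
                    source=ALT_LABEL,
                )
                gene_truth.append(iso)
                edits.append(_Edit(tid, _edit_event_type(kind, strand), window))
                if kind == "IR":
                    ir_ids.add(tid)
        edits_by_gene[gid] = edits
        truth_txs.extend(gene_truth)
        for t in gene_truth:
            (alt_txs if t.source == ALT_LABEL else ref_txs).append(t)

        # --- redundancy injection -------------------------------------
        redundant: list[TranscriptModel] = []
        existing_chains = {t.intron_chain().introns for t in gene_truth}

        # target must itself be spliced: an IR isoform of a 2-exon gene is
        # mono-exon and its UTR variant would fall under the mono-exon rule
        spliced_truth = [t for t in gene_truth if t.n_exons > 1]
        if spliced_truth and rng.random() < rates.utr_variant:
            target = spliced_truth[int(rng.integers(0, len(spliced_truth)))]
            ex = [(e.start, e.end) for e in target.exons]
            d5 = int(rng.integers(10, min(61, ex[0][1] - ex[0][0] - 18)))
            d3 = int(rng.integers(10, min(61, ex[-1][1] - ex[-1][0] - 18)))
            ex[0] = (ex[0][0] + d5, ex[0][1])
            ex[-1] = (ex[-1][0], ex[-1][1] - d3)
            tid = f"{gid}.u1"
            redundant.append(
                TranscriptModel(
                    tid, gid, tuple(_exon(s, e, strand) for s, e in ex),
                    source=REF_LABEL if rng.random() < 0.5 else ALT_LABEL,
                )
            )
            ledger.append(
                TruthEntry(tid, Rule.SAME_CHAIN_SHORTER_UTR, target.transcript_id, gid)
            )

        if mono and rng.random() < rates.monoexon_variant:
            s, e = base[0]
            da, db = int(rng.integers(20, 81)), int(rng.integers(20, 81))
            tid = f"{gid}.m1"
            redundant.append(
                TranscriptModel(
                    tid, gid, (_exon(s + da, e - db, strand),),
                    source=REF_LABEL if rng.random() < 0.5 else ALT_LABEL,
                )
            )
            ledger.append(
                TruthEntry(tid, Rule.MONOEXON_SHORTER, base_tx.transcript_id, gid)
            )

        if not mono and len(base) >= 3 and rng.random() < rates.fragment:
            n = len(base)
            candidates = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if (i, j) != (0, n - 1)
            ]
            rng.shuffle(candidates)
            introns = [(base[i][1] + 1, base[i + 1][0] - 1) for i in range(n - 1)]
            for i, j in candidates:
                chain = tuple(introns[i:j])
                if chain in existing_chains:
                    continue
                ex = [list(x) for x in base[i : j + 1]]
                ex[0][0] += int(rng.integers(5, 41))
                ex[-1][1] -= int(rng.integers(5, 41))
                tid = f"{gid}.f1"
                redundant.append(
                    TranscriptModel(
                        tid, gid,
                        tuple(_exon(s, e, strand) for s, e in ex),
                        source=ALT_LABEL,
                    )
                )
                ledger.append(
                    TruthEntry(tid, Rule.FRAGMENT, base_tx.transcript_id, gid)
                )
                existing_chains.add(chain)
                break

        for t in redundant:
            (alt_txs if t.source == ALT_LABEL else ref_txs).append(t)

        # --- gene spans ------------------------------------------------
        union = GenomicInterval(CHROM, base[0][0], base[-1][1], strand)
        in_ref = any(t.source == REF_LABEL for t in gene_truth + redundant)
        in_alt = any(t.source == ALT_LABEL for t in gene_truth + redundant)
        truth_span = union
        ref_span = alt_span = union
        if in_ref and in_alt:
            u = rng.random()
            if u < rates.contained_gene_model:
                m = int(rng.integers(50, 201))
                wide = GenomicInterval(CHROM, union.start - m, union.end + m, strand)
                if rng.random() < 0.5:
                    ref_span, truth_span = wide, wide
                else:
                    alt_span, truth_span = wide, wide
            elif u < rates.contained_gene_model + rates.partial_overlap_gene_model:
                m1, m2 = int(rng.integers(50, 201)), int(rng.integers(50, 201))
                ref_span = GenomicInterval(CHROM, union.start - m1, union.end, strand)
                alt_span = GenomicInterval(CHROM, union.start, union.end + m2, strand)
                truth_span = ref_span
        elif in_ref:
            pass
        else:
            truth_span = alt_span
        ref_spans[gid] = ref_span
        alt_spans[gid] = alt_span
        truth_spans[gid] = truth_span

        cursor = base[-1][1] + 1 + 1500

    chrom_len = cursor + 1000

    def build(txs, spans, label):
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in txs:
            by_gene.setdefault(t.gene_id, []).append(t)
        genes = {
            gid: GeneModel(gid, tuple(ts), span=spans[gid])
            for gid, ts in by_gene.items()
        }
        return AnnotationSet(genes=genes, source_label=label)

    ref_set = build(ref_txs, ref_spans, REF_LABEL)
    alt_set = build(alt_txs, alt_spans, ALT_LABEL)
    truth_set = build(truth_txs, truth_spans, "rtd")

    events = _build_events(spec, truth_set, edits_by_gene, gene_strand)
    return World(
        spec, chrom_len, ref_set, alt_set, truth_set, ledger, events, ir_ids
    )


def _build_events(
    spec: FixtureSpec,
    truth: AnnotationSet,
    edits_by_gene: dict[str, list[_Edit]],
    gene_strand: dict[str, str],
) -> list[ASEvent]:
    """One fully assigned event per true AS isoform, partition by construction."""
    events = []
    for gid in sorted(edits_by_gene):
        edits = edits_by_gene[gid]
        if not edits:
            continue
        gene = truth.genes[gid]
        all_ids = {t.transcript_id for t in gene.transcripts}
        for k, edit in enumerate(edits, start=1):
            lo, hi = edit.window
            region = GenomicInterval(
                CHROM, lo - spec.flank, hi + spec.flank, gene_strand[gid]
            )
            pos = {edit.transcript_id}
            other = {
                e.transcript_id
                for e in edits
                if e.transcript_id != edit.transcript_id
                and e.window[0] <= region.end
                and region.start <= e.window[1]
            }
            fs = all_ids - pos - other
            events.append(
                ASEvent(
                    f"E_{gid}_{k}",
                    gid,
                    edit.event_type,
                    region,
                    frozenset(pos),
                    frozenset(fs),
                    frozenset(other),
                )
            )
    return events


def generate_annotation_pair(
    spec: FixtureSpec,
) -> tuple[AnnotationSet, AnnotationSet, AnnotationSet, list[TruthEntry]]:
    """(reference, discovery, nonredundant truth, truth ledger) for one seed."""
    w = generate_world(spec)
    return w.ref, w.alt, w.truth, w.truth_ledger


def generate_genome(spec: FixtureSpec) -> str:
    """FASTA text of a random genome long enough to host all generated genes."""
    w = generate_world(spec)
    rng = np.random.default_rng([1, spec.seed])
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=w.chrom_len)
    text = seq.tobytes().decode()
    lines = [f">{CHROM}"]
    lines.extend(text[i : i + 60] for i in range(0, len(text), 60))
    return "\n".join(lines) + "\n"


def generate_abundance_and_peaks(
    truth: AnnotationSet,
    events: list[ASEvent],
    spec: FixtureSpec,
) -> tuple[AbundanceTable, PeakTable, list[RatioRecord]]:
    """Paired TPM / peak-area tables with known true splicing ratios.

    Per transcript and time-point a latent abundance is drawn log-normally;
    each biological replicate perturbs it by a log-normal factor of scale
    ``bio_sd`` (shared truth for both methods). TPM is the per-sample
    normalization of the latent abundances; peak areas are category sums of
    the same latent abundances times a log-normal measurement factor of
    scale ``noise_sd`` — at ``noise_sd = 0`` the two methods agree exactly.
    """
    rng = np.random.default_rng([2, spec.seed])
    samples = [
        SampleInfo(f"{tp}_R{r}", tp, r)
        for tp in spec.time_points
        for r in range(1, spec.n_replicates + 1)
    ]
    tids = sorted(t.transcript_id for t in truth.transcripts())
    tp_index = {tp: i for i, tp in enumerate(spec.time_points)}
    base = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=(len(tids), len(spec.time_points)))
    latent = np.empty((len(tids), len(samples)))
    for j, s in enumerate(samples):
        bio = (
            rng.lognormal(0.0, spec.bio_sd, size=len(tids))
            if spec.bio_sd > 0
            else np.ones(len(tids))
        )
        latent[:, j] = base[:, tp_index[s.time_point]] * bio

    tpm = latent / latent.sum(axis=0, keepdims=True) * 1e6
    df = pd.DataFrame(tpm, index=tids, columns=[s.sample_id for s in samples])
    abundance = AbundanceTable(df, samples)

    idx = {tid: i for i, tid in enumerate(tids)}
    gain = 0.8
    peaks = PeakTable()
    true_ratios: list[RatioRecord] = []
    for e in events:
        cat_ids = {"positive": e.positive_ids, "fs": e.fs_ids, "other": e.other_ids}
        for j, s in enumerate(samples):
            sums = {
                cat: float(sum(latent[idx[t], j] for t in ids))
                for cat, ids in cat_ids.items()
            }
            for cat, ids in cat_ids.items():
                if not ids:
                    continue
                noise = (
                    float(rng.lognormal(0.0, spec.noise_sd))
                    if spec.noise_sd > 0
                    else 1.0
                )
                peaks.add(e.event_id, cat.upper(), cat, s.sample_id, sums[cat] * gain * noise)
            total = sums["positive"] + sums["fs"] + sums["other"]
            for mode, num, den in (
                ("of_total", sums["positive"], total),
                ("as_vs_fs", sums["positive"], sums["positive"] + sums["fs"]),
            ):
                true_ratios.append(
                    RatioRecord(
                        e.event_id,
                        s.sample_id,
                        "truth",
                        mode,
                        num / den if den > 0 else float("nan"),
                        den > 0,
                    )
                )
    return abundance, peaks, true_ratios
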