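"""Event-level splicing ratios from transcript abundances and RT-PCR peak areas.

An alternative-splicing event is assayed over a primer-pair region. Within
that region every transcript of the gene is either event-positive (it
carries the event), fully spliced (it matches the canonical spliced
structure of the region), or "other" (a different local structure).
Ratios are computed per sample in two modes:

``of_total``
    event-positive abundance over total assigned abundance — the share of
    the gene's output carrying the event.
``as_vs_fs``
    event-positive abundance over (event-positive + fully spliced) — robust
    when some isoforms are detected by one method only. A raw AS/FS
    quotient (unbounded) is available for sensitivity analysis.

The same formulas apply to TPM (RNA-seq quantification) and RFU peak areas
(high-resolution RT-PCR), making the two methods directly comparable by
Pearson and Spearman correlation over events x samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyEventError,
    FormatError,
    InsufficientDataError,
    ValidationError,
)
from .model import AnnotationSet, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

EVENT_TYPES = ("IR", "Alt5", "Alt3", "ES")
MODES = ("of_total", "as_vs_fs")
PEAK_CATEGORIES = ("positive", "fs", "other")


@dataclass(frozen=True)
class SampleInfo:
    """One quantified sample: a (time-point, biological replicate) pair."""

    sample_id: str
    time_point: str
    replicate: int


@dataclass
class AbundanceTable:
    """Transcript x sample TPM matrix with sample metadata.

    Missing (transcript, sample) entries read as 0 TPM; lookups of unknown
    transcripts are counted and logged, not fatal, so the table can be used
    with any transcript dataset.
    """

    df: pd.DataFrame  # index: transcript_id, columns: sample_id
    samples: list[SampleInfo]
    n_missing_lookups: int = 0

    def __post_init__(self) -> None:
        if (self.df.to_numpy() < 0).any():
            raise ValidationError("negative TPM in abundance table")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def time_point_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.time_point
        raise KeyError(sample_id)

    def tpm(self, transcript_id: str, sample_id: str) -> float:
        if transcript_id not in self.df.index:
            self.n_missing_lookups += 1
            if self.n_missing_lookups == 1:
                logger.info("abundance table: unknown transcripts read as 0 TPM")
            return 0.0
        return float(self.df.at[transcript_id, sample_id])

    def total(self, transcript_ids, sample_id: str) -> float:
        return sum(self.tpm(t, sample_id) for t in sorted(transcript_ids))


_NAME_COLS = ("name", "transcript", "transcript_id", "target_id", "id")


def read_quant(path: str | Path, sample: SampleInfo) -> AbundanceTable:
    """Read one Sailfish/Salmon-style quantification table (one sample).

    Requires a tab-delimited file with a transcript-name column and a TPM
    column (case-insensitive header match).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.lower(): c for c in df.columns}
    name_col = next((lower[c] for c in _NAME_COLS if c in lower), None)
    tpm_col = lower.get("tpm")
    if name_col is None or tpm_col is None:
        raise FormatError(
            f"{path}: need a transcript-name column and a TPM column, "
            f"header was {list(df.columns)}"
        )
    if (df[tpm_col] < 0).any():
        raise ValidationError(f"{path}: negative TPM values")
    out = df[[name_col, tpm_col]].set_index(name_col)
    out.columns = [sample.sample_id]
    return AbundanceTable(out, [sample])


def load_quant_tables(files: list[tuple[SampleInfo, str | Path]]) -> AbundanceTable:
    """Merge per-sample quantification files into one table, in given order."""
    if not files:
        raise ValueError("no quantification files given")
    tables = [read_quant(path, sample) for sample, path in files]
    df = pd.concat([t.df for t in tables], axis=1).fillna(0.0)
    return AbundanceTable(df, [t.samples[0] for t in tables])


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event and its transcript partition."""

    event_id: str
    gene_id: str
    event_type: str
    region: GenomicInterval
    positive_ids: frozenset[str] = frozenset()
    fs_ids: frozenset[str] = frozenset()
    other_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        sets = (self.positive_ids, self.fs_ids, self.other_ids)
        total = sum(map(len, sets))
        if total != len(self.positive_ids | self.fs_ids | self.other_ids):
            raise ValidationError(
                f"event {self.event_id}: transcript categories overlap"
            )

    @property
    def assigned(self) -> bool:
        return bool(self.positive_ids | self.fs_ids | self.other_ids)

    @property
    def all_ids(self) -> frozenset[str]:
        return self.positive_ids | self.fs_ids | self.other_ids


def _local_introns(t: TranscriptModel, region: GenomicInterval):
    return tuple(
        iv
        for iv in t.intron_chain().introns
        if iv[0] <= region.end and region.start <= iv[1]
    )


def _classify_local(
    local: tuple,
    fs_local: tuple,
    t: TranscriptModel,
    strand: str,
    region: GenomicInterval,
) -> str:
    """Event class of a transcript's local structure relative to fully spliced.

    An event is only called when its defining intron boundaries lie fully
    inside the assayed region; a structural difference whose boundaries
    escape the region (e.g. a skipped exon splicing to an acceptor beyond
    the primer pair) is a different product, classed "other".
    """
    if local == fs_local:
        return "fs"

    def inside(iv: tuple[int, int]) -> bool:
        return region.start <= iv[0] and iv[1] <= region.end

    missing = [iv for iv in fs_local if iv not in local]
    extra = [iv for iv in local if iv not in fs_local]
    if len(missing) == 1 and not extra and inside(missing[0]):
        s, e = missing[0]
        # retained iff a single exon covers the whole intron
        if any(ex.start <= s and e <= ex.end for ex in t.exons):
            return "IR"
        return "other"
    if len(missing) == 1 and len(extra) == 1 and inside(missing[0]) and inside(extra[0]):
        (ms, me), (xs, xe) = missing[0], extra[0]
        if ms == xs and me != xe:
            # right boundary (acceptor on +, donor on -) shifted
            return "Alt3" if strand == "+" else "Alt5"
        if me == xe and ms != xs:
            return "Alt5" if strand == "+" else "Alt3"
        return "other"
    if len(missing) == 2 and len(extra) == 1:
        if all(map(inside, missing)) and inside(extra[0]):
            (a, _), (_, d) = sorted(missing)[0], sorted(missing)[1]
            if extra[0] == (a, d):
                return "ES"  # the exon between the two introns is skipped
    return "other"


def assign_transcripts_to_event(
    template: ASEvent, rtd: AnnotationSet
) -> ASEvent:
    """Partition a gene's transcripts over an event region by local structure.

    The fully spliced reference structure of the region is the local intron
    set removing the most sequence: maximal intron count, then maximal total
    intron length (ties broken lexicographically for determinism).
    Transcripts not overlapping the region are excluded from all categories.
    Templates that already carry explicit assignments are returned as-is.
    """
    if template.assigned:
        return template
    gene = rtd.genes.get(template.gene_id)
    if gene is None:
        raise KeyError(template.gene_id)
    region = template.region
    overlapping = [t for t in gene.transcripts if t.span.overlaps(region)]
    if not overlapping:
        raise EmptyEventError(
            f"event {template.event_id}: no transcript overlaps "
            f"{region.chrom}:{region.start}-{region.end}"
        )
    locals_ = {t.transcript_id: _local_introns(t, region) for t in overlapping}

    def n_junctions(L: tuple) -> int:
        # splice junctions falling inside the region: an event isoform either
        # loses junctions (IR, ES) or keeps the same count (Alt5/Alt3)
        return sum(
            (region.start <= s <= region.end) + (region.start <= e <= region.end)
            for s, e in L
        )

    # canonical fully-spliced structure: maximal junction count; among tied
    # structures (e.g. two alternative acceptors) the one carried by the
    # earliest-named transcript — annotation convention lists the canonical
    # isoform first (.1 before .2 or discovery-suffixed ids)
    carrier: dict[tuple, str] = {}
    for tid in sorted(locals_):
        carrier.setdefault(locals_[tid], tid)
    best = max(map(n_junctions, carrier))
    fs_local = min(
        (L for L in carrier if n_junctions(L) == best), key=lambda L: carrier[L]
    )
    pos, fs, other = set(), set(), set()
    for t in overlapping:
        cls = _classify_local(locals_[t.transcript_id], fs_local, t, t.strand, region)
        if cls == "fs":
            fs.add(t.transcript_id)
        elif cls == template.event_type:
            pos.add(t.transcript_id)
        else:
            other.add(t.transcript_id)
    return ASEvent(
        template.event_id,
        template.gene_id,
        template.event_type,
        region,
        frozenset(pos),
        frozenset(fs),
        frozenset(other),
    )


def read_events(path: str | Path) -> list[ASEvent]:
    """Read an event-definition TSV.

    Columns: event_id, gene_id, event_type, chrom, start, end, strand, and
    optionally positive_ids / fs_ids / other_ids (comma-separated) to
    override automatic assignment.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"event_id", "gene_id", "event_type", "chrom", "start", "end", "strand"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    events = []
    for row in df.itertuples(index=False):
        region = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        explicit = {}
        for col in ("positive_ids", "fs_ids", "other_ids"):
            val = getattr(row, col, None)
            if isinstance(val, str) and val.strip():
                explicit[col] = frozenset(val.split(","))
        events.append(
            ASEvent(row.event_id, row.gene_id, row.event_type, region, **explicit)
        )
    return events


@dataclass(frozen=True)
class RatioRecord:
    """One splicing ratio: event x sample x method x mode."""

    event_id: str
    sample_id: str
    method: str  # rnaseq | hrrtpcr
    mode: str  # of_total | as_vs_fs | as_vs_fs_raw
    ratio: float
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and self.mode in MODES and not 0.0 <= self.ratio <= 1.0:
            raise ValidationError(
                f"{self.event_id}/{self.sample_id}: ratio {self.ratio} out of [0,1]"
            )


def _record(event_id, sample_id, method, mode, num, den) -> RatioRecord:
    if den <= 0:
        return RatioRecord(event_id, sample_id, method, mode, float("nan"), False)
    return RatioRecord(event_id, sample_id, method, mode, num / den, True)


def ratio_of_total(e: ASEvent, a: AbundanceTable, sample_id: str) -> RatioRecord:
    """Event-positive TPM over total assigned TPM."""
    num = a.total(e.positive_ids, sample_id)
    den = a.total(e.all_ids, sample_id)
    return _record(e.event_id, sample_id, "rnaseq", "of_total", num, den)


def ratio_as_vs_fs(
    e: ASEvent, a: AbundanceTable, sample_id: str, raw: bool = False
) -> RatioRecord:
    """Event-positive TPM relative to fully spliced TPM.

    Default is the bounded AS/(AS+FS) fraction; ``raw=True`` emits the
    unbounded AS/FS quotient instead.
    """
    num = a.total(e.positive_ids, sample_id)
    fs = a.total(e.fs_ids, sample_id)
    if raw:
        return _record(e.event_id, sample_id, "rnaseq", "as_vs_fs_raw", num, fs)
    return _record(e.event_id, sample_id, "rnaseq", "as_vs_fs", num, num + fs)


@dataclass
class PeakTable:
    """RT-PCR peak areas: (event, product, sample) -> RFU, with a product
    -> category map saying which ratio term each product feeds."""

    values: dict[tuple[str, str, str], float] = field(default_factory=dict)
    categories: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(
        self, event_id: str, product_label: str, category: str, sample_id: str, rfu: float
    ) -> None:
        if category not in PEAK_CATEGORIES:
            raise ValidationError(
                f"product {product_label} of {event_id}: unknown category "
                f"{category!r} (need one of {PEAK_CATEGORIES})"
            )
        if rfu < 0:
            raise ValidationError(f"negative RFU for {event_id}/{product_label}")
        self.values[(event_id, product_label, sample_id)] = rfu
        prev = self.categories.setdefault((event_id, product_label), category)
        if prev != category:
            raise ValidationError(
                f"product {product_label} of {event_id} labelled both "
                f"{prev!r} and {category!r}"
            )

    def category_total(self, event_id: str, category: str, sample_id: str) -> float:
        tot = 0.0
        for (ev, prod, sid), rfu in self.values.items():
            if ev == event_id and sid == sample_id:
                cat = self.categories.get((ev, prod))
                if cat is None:
                    raise ValidationError(f"unlabelled product {prod} of {ev}")
                if cat == category:
                    tot += rfu
        return tot


def read_peaks(path: str | Path) -> PeakTable:
    """Read a peak-area TSV: event_id, product_label, category, sample_id, rfu."""
    df = pd.read_csv(path, sep="\t", dtype={"rfu": float})
    required = {"event_id", "product_label", "category", "sample_id", "rfu"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    table = PeakTable()
    for row in df.itertuples(index=False):
        table.add(row.event_id, row.product_label, row.category, row.sample_id, row.rfu)
    return table


def pcr_ratio(
    p: PeakTable, e: ASEvent, sample_id: str, mode: str = "as_vs_fs", raw: bool = False
) -> RatioRecord:
    """Splicing ratio from peak areas, same formulas as the TPM ratios."""
    pos = p.category_total(e.event_id, "positive", sample_id)
    fs = p.category_total(e.event_id, "fs", sample_id)
    if mode == "of_total":
        other = p.category_total(e.event_id, "other", sample_id)
        return _record(e.event_id, sample_id, "hrrtpcr", mode, pos, pos + fs + other)
    if mode != "as_vs_fs":
        raise ValueError(f"unknown mode {mode!r}")
    if raw:
        return _record(e.event_id, sample_id, "hrrtpcr", "as_vs_fs_raw", pos, fs)
    return _record(e.event_id, sample_id, "hrrtpcr", "as_vs_fs", pos, pos + fs)


@dataclass(frozen=True)
class ReplicateStats:
    """Mean +/- SD over biological replicates for one (event, time-point, method)."""

    event_id: str
    time_point: str
    method: str
    mode: str
    mean: float
    sd: float | None  # None for a single valid replicate
    n: int


def aggregate_replicates(
    records: list[RatioRecord], time_points: dict[str, str]
) -> list[ReplicateStats]:
    """Collapse replicate ratios to mean and sample SD (ddof=1) per group.

    ``time_points`` maps sample_id to its time-point label. Groups with no
    valid record are dropped with a warning; a single valid record reports
    its value with SD absent.
    """
    groups: dict[tuple[str, str, str, str], list[float]] = {}
    dropped: set[tuple] = set()
    for r in records:
        key = (r.event_id, time_points[r.sample_id], r.method, r.mode)
        if r.valid:
            groups.setdefault(key, []).append(r.ratio)
        else:
            dropped.add(key)
    for key in dropped - set(groups):
        logger.warning("group %s has no valid replicate; dropped", key)
    out = []
    for key in sorted(groups):
        vals = groups[key]
        if len(vals) == 1:
            sd = None
        elif len(set(vals)) == 1:
            sd = 0.0  # constant replicates: exactly zero, no float round-trip
        else:
            sd = float(np.std(vals, ddof=1))
        out.append(ReplicateStats(*key, float(np.mean(vals)), sd, len(vals)))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float | None
    spearman_rho: float | None
    n_points: int


def pair_records(
    rnaseq: list[RatioRecord], pcr: list[RatioRecord]
) -> list[tuple[float, float]]:
    """Match records on (event, sample, mode); keep pairs where both are valid."""
    by_key = {
        (r.event_id, r.sample_id, r.mode): r for r in pcr if r.valid
    }
    pairs = []
    for r in rnaseq:
        if not r.valid:
            continue
        q = by_key.get((r.event_id, r.sample_id, r.mode))
        if q is not None:
            pairs.append((r.ratio, q.ratio))
    return pairs


def correlate(pairs: list[tuple[float, float]]) -> CorrelationResult:
    """Pearson and Spearman (average-rank ties) correlation of paired ratios."""
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"need at least 2 paired points, got {len(pairs)}"
        )
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(None, None, len(pairs))
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(r, rho, len(pairs))


def compare_methods(
    events: list[ASEvent],
    abundance: AbundanceTable,
    peaks: PeakTable,
    mode: str = "as_vs_fs",
    raw: bool = False,
) -> tuple[list[RatioRecord], list[RatioRecord], CorrelationResult]:
    """Per-replicate ratios for both methods plus their correlation.

    Every (event, sample) replicate contributes one point per method;
    replicates are correlated as individual points, not as means.
    """
    rna: list[RatioRecord] = []
    pcr: list[RatioRecord] = []
    for e in events:
        for sid in abundance.sample_ids:
            if mode == "of_total":
                rna.append(ratio_of_total(e, abundance, sid))
            else:
                rna.append(ratio_as_vs_fs(e, abundance, sid, raw=raw))
            pcr.append(pcr_ratio(peaks, e, sid, mode=mode, raw=raw))
    result = correlate(pair_records(rna, pcr))
    return rna, pcr, result
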