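# Methods

## The construction model

An annotation source is a set of gene models; a gene model is a declared
span plus transcript models; a transcript model is an ordered run of
pairwise non-adjacent exons on one strand of one chromosome. Coordinates
are 1-based inclusive everywhere (the convention shared by GTF and GFF3);
any half-open arithmetic is internal to individual functions. Gene and
transcript identity is taken from `gene_id`/`transcript_id` (GTF) and
`ID`/`Parent` (GFF3) attributes — the pipeline assumes the sources share
gene identifiers and performs no positional gene inference, no fusion or
fission detection, and no re-assignment of transcripts between genes.
Non-exon sub-features (CDS, UTR lines) are ignored: redundancy is decided
on intron coordinates alone, and UTR extents are exactly what the rules
are designed to disregard.

### Span reconciliation

For each gene id in the union of the two sources the declared spans are
compared. Containment (including equality) keeps the larger span, with the
reference span winning exact ties; partial overlap keeps the reference
span. Two cases the geometry does not force are handled conservatively:

- same-id spans that are *disjoint* resolve to the reference span with a
  warning and an explicit `disjoint_keep_ref` tag in the pairing report —
  nothing is deleted;
- a transcript extending outside the resolved span widens the span
  (with a warning) rather than being cropped or dropped.

Removing the "smaller" gene model removes only its coordinate record:
transcripts of both sources always survive into deduplication. Merged
source counts in real datasets make clear that transcripts from both
sources are retained and thinned later, not discarded wholesale.

### Deduplication rules

All three rules operate per gene, in a fixed order, and log one decision
per removal.

1. **Identical intron chains.** Spliced transcripts with equal chains have
   identical internal structure; the survivor is the one with the largest
   *spliced* length (genomic span would reward long introns, not long
   UTRs). Ties prefer the reference-source transcript, then the
   lexicographically smallest id, making builds reproducible.
2. **Mono-exon variants.** Mono-exon transcripts are processed in
   descending length; one is removed iff it overlaps an already-retained
   strictly longer same-strand mono-exon transcript (or an equal-length
   one with an identical span). Non-overlapping mono-exon transcripts of a
   gene are genuinely distinct and all kept.
3. **Fragments.** `is_fragment(short, long)` requires (a) `short`'s span
   inside `long`'s with at least one end strictly inside, (b) every intron
   of `short` present in `long`'s chain, and (c) every intron of `long`
   strictly inside `short`'s span present in `short`'s chain. Condition
   (c) is the intron-retention guard: a retained intron within the
   fragment candidate's span marks it as a genuine isoform. Span-equal
   transcripts are never fragments by (a) — in particular a fully spliced
   parent is never removed in favour of its longer IR isoform. Removal is
   processed in descending spliced length so a removed fragment can never
   shield another; the decision names the longest retained match.

Whether a fragment must be strictly inside on *both* ends is not
determined by the informal description the rule descends from; this
implementation requires one strict end, the weaker and therefore more
aggressive reading, and relies on conditions (b)–(c) for safety. UTR
redundancy *within* a single source is collapsed in the same unified pass
as cross-source redundancy.

### Curated merge

Curated transcripts (e.g. variants confirmed by targeted RT-PCR) are added
after automated construction. They are exempt from removal but participate
as removers, so a curated model displaces an automated same-chain shorter
duplicate. An id collision with a different exon structure is an error, not
a silent rename. The rules are re-run on touched genes, so the final set is
again a fixed point: rebuilding any output produces zero decisions.

## Event assignment and splicing ratios

An AS event is a (gene, type, region) triple, the region being the span a
primer pair would assay. Transcripts overlapping the region are classified
by their *local* intron set (introns intersecting the region):

- The canonical fully spliced (FS) structure is the local set with the
  most splice junctions inside the region. Junction-count ties — two
  alternative acceptors are structurally symmetric, and either may remove
  more sequence — are broken by the earliest-named carrier transcript,
  matching the annotation convention that the canonical isoform is `.1`.
  Explicit per-event transcript assignments in the event table override
  the automatic rule entirely.
- Relative to FS, a transcript is IR (one FS intron missing and covered by
  an exon), Alt5/Alt3 (one intron substituted with one boundary shared;
  which label depends on strand), or ES (two consecutive FS introns and
  the exon between replaced by their union). The defining boundaries must
  lie fully inside the region; a structural difference escaping the region
  (e.g. a skipped exon splicing to an acceptor beyond the primer) is a
  different product and classed "other".
- Transcripts matching the event's type are event-positive; those matching
  FS are fully spliced; the rest are "other". Transcripts not overlapping
  the region are excluded from all categories.

Ratios per sample: `of_total = AS/(AS+FS+other)` and
`as_vs_fs = AS/(AS+FS)`; both are fractions in [0, 1]. The bounded
AS/(AS+FS) form is the default for method comparison because it remains
stable when the FS denominator is small; the raw AS/FS quotient is
available behind a flag for sensitivity analysis. A zero denominator yields
an invalid record rather than an error; invalid records are excluded
pairwise from correlation, which mirrors the practical situation where one
method detects a low-abundance product the other misses. Replicates enter
the correlation as individual points (not means); replicate summaries are
mean ± sample SD (ddof = 1), with SD reported absent for a single valid
replicate and exactly 0.0 for bit-identical replicate values. Spearman uses
average ranks on ties; if either vector has zero variance both coefficients
are reported absent.

## The synthetic world

The generator emulates a two-source merge and a paired two-method
validation experiment on one chromosome. Per gene (defaults in
parentheses): mono-exon with probability 0.15, otherwise 2–6 exons of
100–300 bp separated by introns of 80–250 bp; extra true isoforms per
spliced gene ~ Poisson(1.2) capped at 3, realized as IR, Alt5/Alt3
(boundary shifted 3–12 nt into the intron) or ES edits, each
(intron, type) slot used at most once so event partitions are unambiguous
by construction. These choices target the isoform complexity of a merged
plant RTD — roughly two transcripts per gene with IR and alternative
splice-site events dominating. All isoform edits preserve the terminal
exons, so true isoforms are span-equal and provably immune to the fragment
rule; IR isoforms are tracked separately for the safety checks.

Injected redundancy (per-gene probabilities, default 0.5 for the three
transcript classes and 0.3 for the two gene-span classes): a same-chain
UTR variant trimmed 10–60 bp at each terminal exon; a contained shorter
mono-exon variant; a fragment spanning a proper sub-run of the base
transcript's exons with trimmed outer ends, injected only when its chain
collides with no existing transcript so exactly one rule fires for it; and
gene-span containment / partial-overlap perturbations of 50–200 bp. The
truth ledger records every injected transcript with its expected removal
rule; recovery is asserted on (removed_id, rule) multisets because the
kept partner of a fragment is a tie-break (the longest retained match),
not ground truth.

Measurements: each transcript gets a latent log-normal abundance per
time-point (median 20, σ = 1), perturbed per biological replicate by a
log-normal factor (σ = 0.15) shared by both methods — 3 replicates × 2
time-points. TPM is the per-sample normalization of the latent abundances;
peak areas are category sums of the same latent abundances times a gain
and a log-normal measurement factor (σ = 0.25 by default). At zero
measurement noise the two methods' ratios are identical by construction,
which is the calibration the validation statistics are checked against.
What the generator does *not* emulate: read-level sampling noise,
positional/GC bias, quantifier-specific estimation error, and incomplete
transcript catalogues — so passing tests demonstrate the correctness of
the construction and ratio machinery, not the field accuracy of any
particular quantification tool.

## Numerical and degenerate-input choices

- Presentation rounding (per-gene averages, AS percentage) is two decimals,
  half away from zero, via decimal arithmetic.
- Averages and percentages with zero denominators are reported absent
  (`None`), not 0 and not an exception, in summaries; explicitly requested
  division by zero genes raises.
- Empty annotation files parse to empty sets; building from two empty sets
  yields an empty dataset and no decisions.
- Written annotations are normalized (genes by position, exons ascending,
  fixed gene-line source), so write∘read is a fixed point and file-level
  diffs are meaningful.
- Unsorted exons in inputs are sorted with a warning; a transcript on two
  strands or chromosomes is an error.
- Unknown transcripts in abundance lookups read as 0 TPM with a logged
  count, so quantifications against a superset reference remain usable.

## Problem sizes

The bundled checks run the recovery suite at 200 genes × 10 seeds × 3
redundancy rates, idempotence at 100 datasets of 20 genes, oracle
equivalence over all generated genes with ≤ 8 transcripts, and the
method-comparison calibration at 50 events × 6 samples (300 paired
points) — sizes chosen so the full suite and the acceptance script each
complete in seconds while still exercising every rule many hundreds of
times.

## Known limitations

- Cross-source gene pairing is by shared identifier only; discovery genes
  with novel ids are carried through unmatched rather than anchored by
  position.
- The automatic FS canonicalization depends on transcript naming when
  junction counts tie; for real assays the explicit assignment columns of
  the event table are the authoritative route.
- Mono-exon collapse uses greedy longest-first overlap, which can differ
  from a global clique treatment on pathological overlap chains.
- No CDS/protein awareness: a UTR variant that changes coding potential is
  still collapsed if its intron chain is identical.
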