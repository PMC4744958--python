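"""Intron chains, the three redundancy rules, curated merge, and the full build.

Brute-force oracles: each rule's survivor set is recomputed here by an
independent fixpoint over all transcript pairs and compared with the
implementation on generated genes.
"""

import itertools

import pytest

from rtdkit import (
    AnnotationSet,
    DedupConfig,
    FixtureSpec,
    RedundancyRates,
    Rule,
    build_rtd,
    collapse_identical_chains,
    collapse_monoexon,
    generate_annotation_pair,
    generate_world,
    is_fragment,
    merge_curated,
    remove_fragments,
)
from rtdkit.errors import ConflictError

from conftest import aset, tx


def gene_of(*transcripts):
    return aset(list(transcripts)).genes[transcripts[0].gene_id]


# --- intron_chain ----------------------------------------------------------


@pytest.mark.parametrize(
    "exons,introns",
    [
        ([(1, 100), (201, 300)], [(101, 200)]),
        ([(1, 500)], []),
        ([(1, 10), (21, 30), (41, 50)], [(11, 20), (31, 40)]),
    ],
)
def test_intron_chain_from_exons(exons, introns):
    assert list(tx("t", "g", exons).intron_chain().introns) == introns


# --- collapse_identical_chains --------------------------------------------


def test_same_chain_keeps_longest_spliced():
    long = tx("t1", "g", [(1, 100), (201, 900)])
    short = tx("t2", "g", [(50, 100), (201, 850)])
    g, dec = collapse_identical_chains(gene_of(long, short))
    assert {t.transcript_id for t in g.transcripts} == {"t1"}
    assert dec == [_d("t2", "t1", Rule.SAME_CHAIN_SHORTER_UTR)]


def test_different_chains_both_kept():
    a = tx("t1", "g", [(1, 100), (201, 300)])
    b = tx("t2", "g", [(1, 110), (201, 300)])
    g, dec = collapse_identical_chains(gene_of(a, b))
    assert g.n_transcripts == 2 and not dec


def test_two_chain_groups_match_brute_force():
    """Five transcripts over two chains -> 2 survivors = argmax length per group."""
    txs = [
        tx("a1", "g", [(1, 100), (201, 300)]),
        tx("a2", "g", [(10, 100), (201, 290)]),
        tx("a3", "g", [(5, 100), (201, 299)]),
        tx("b1", "g", [(1, 120), (221, 300)]),
        tx("b2", "g", [(8, 120), (221, 280)]),
    ]
    g, dec = collapse_identical_chains(gene_of(*txs))
    expected = _oracle_chain_collapse(txs)
    assert {t.transcript_id for t in g.transcripts} == expected
    assert len(dec) == 3


# --- collapse_monoexon -----------------------------------------------------


def test_monoexon_overlapping_keeps_longest():
    a, b = tx("t1", "g", [(1, 1000)]), tx("t2", "g", [(50, 900)])
    g, dec = collapse_monoexon(gene_of(a, b))
    assert {t.transcript_id for t in g.transcripts} == {"t1"}
    assert dec == [_d("t2", "t1", Rule.MONOEXON_SHORTER)]


def test_monoexon_rule_ignores_spliced_transcripts():
    mono = tx("t1", "g", [(1, 1000)])
    spliced = tx("t2", "g", [(1, 400), (600, 1000)])
    g, dec = collapse_monoexon(gene_of(mono, spliced))
    assert g.n_transcripts == 2 and not dec


def test_nonoverlapping_monoexon_all_kept():
    g, dec = collapse_monoexon(
        gene_of(tx("t1", "g", [(1, 100)]), tx("t2", "g", [(500, 900)]))
    )
    assert g.n_transcripts == 2 and not dec


def test_three_overlapping_monoexon_match_brute_force():
    txs = [
        tx("t1", "g", [(1, 800)]),
        tx("t2", "g", [(100, 900)]),
        tx("t3", "g", [(200, 1400)]),
    ]
    g, dec = collapse_monoexon(gene_of(*txs))
    assert {t.transcript_id for t in g.transcripts} == _oracle_monoexon(txs)
    assert {t.transcript_id for t in g.transcripts} == {"t3"}
    assert len(dec) == 2


# --- is_fragment -----------------------------------------------------------

LONG = tx("L", "g", [(1, 100), (201, 300), (401, 600)])  # introns (101,200),(301,400)


def test_fragment_predicate_true_case():
    short = tx("S", "g", [(150, 300), (401, 500)])  # intron (301,400) only
    assert is_fragment(short, LONG)


def test_span_equal_chain_subset_is_not_fragment():
    """Condition (a): span-identical transcripts are isoforms, never fragments.

    An intron-retention isoform is longer than its parent (it keeps intron
    sequence), so the threatened direction is the fully spliced parent
    against the IR isoform — and equal spans must protect it.
    """
    ir = tx("I", "g", [(1, 100), (201, 600)])  # retains intron 2, same span
    assert LONG.spliced_length < ir.spliced_length
    assert not is_fragment(LONG, ir)


def test_novel_intron_is_not_fragment():
    other = tx("O", "g", [(150, 290), (401, 500)])  # intron (291,400) not in LONG
    assert not is_fragment(other, LONG)


def test_unspliced_intron_inside_span_is_not_fragment():
    """Condition (c): an intron of long inside short's span must be spliced.

    A truncated transcript that retains intron 1 of LONG inside its span is
    a genuine (partial) IR isoform, not a coverage fragment.
    """
    short = tx("S", "g", [(50, 300), (401, 500)])  # covers intron 1 unspliced
    assert short.spliced_length < LONG.spliced_length
    assert set(short.intron_chain().introns) <= set(LONG.intron_chain().introns)
    assert not is_fragment(short, LONG)


def test_fragment_precondition_violations_raise():
    with pytest.raises(ValueError):
        is_fragment(LONG, tx("x", "g", [(1, 50)]))  # long not longer
    with pytest.raises(ValueError):
        is_fragment(tx("y", "other", [(150, 250)]), LONG)


# --- remove_fragments ------------------------------------------------------


def test_remove_fragments_identity_when_no_pair_matches():
    a = tx("t1", "g", [(1, 100), (201, 300)])
    b = tx("t2", "g", [(1, 100), (221, 300)])
    g, dec = remove_fragments(gene_of(a, b))
    assert g.n_transcripts == 2 and not dec


def test_chain_fragment_inside_full_length_removed():
    frag = tx("F", "g", [(150, 300), (401, 500)])
    g, dec = remove_fragments(gene_of(LONG, frag))
    assert {t.transcript_id for t in g.transcripts} == {"L"}
    assert dec == [_d("F", "L", Rule.FRAGMENT)]


def test_nested_fragments_both_name_outermost():
    """A > B > C: B and C both removed, decisions name A."""
    a = tx("A", "g", [(1, 100), (201, 300), (401, 600)])
    b = tx("B", "g", [(50, 100), (201, 300), (401, 550)])
    c = tx("C", "g", [(80, 100), (201, 300), (401, 500)])
    g, dec = remove_fragments(gene_of(a, b, c))
    assert {t.transcript_id for t in g.transcripts} == {"A"}
    assert sorted((d.removed_transcript_id, d.kept_transcript_id) for d in dec) == [
        ("B", "A"),
        ("C", "A"),
    ]


# --- brute-force oracles ---------------------------------------------------


def _d(removed, kept, rule, gene="g"):
    from rtdkit.dedup import DedupDecision

    return DedupDecision(removed, kept, rule, gene)


def _pref(t):
    return (-t.spliced_length, t.transcript_id)


def _oracle_chain_collapse(txs):
    """Independent scan: argmax spliced length per distinct nonempty chain."""
    survivors = set()
    keyfn = lambda t: t.intron_chain().introns
    spliced = sorted((t for t in txs if t.n_exons > 1), key=keyfn)
    for _, grp in itertools.groupby(spliced, key=keyfn):
        survivors.add(min(grp, key=_pref).transcript_id)
    survivors |= {t.transcript_id for t in txs if t.n_exons == 1}
    return survivors


def _oracle_monoexon(txs):
    """Fixpoint: drop any mono-exon transcript overlapped by a surviving
    strictly longer (or equal-length, span-identical) same-strand one."""
    alive = {t.transcript_id: t for t in txs if t.n_exons == 1}
    changed = True
    while changed:
        changed = False
        for a, b in itertools.permutations(list(alive.values()), 2):
            dominated = b.spliced_length > a.spliced_length or (
                b.spliced_length == a.spliced_length and b.span == a.span
                and _pref(b) < _pref(a)
            )
            if a.strand == b.strand and a.span.overlaps(b.span) and dominated:
                del alive[a.transcript_id]
                changed = True
                break
    return set(alive) | {t.transcript_id for t in txs if t.n_exons > 1}


def _oracle_fragments(txs):
    """Fixpoint over all ordered pairs of surviving transcripts."""
    alive = {t.transcript_id: t for t in txs}
    changed = True
    while changed:
        changed = False
        for a, b in itertools.permutations(list(alive.values()), 2):
            if b.spliced_length > a.spliced_length and is_fragment(a, b):
                del alive[a.transcript_id]
                changed = True
                break
    return set(alive)


@pytest.mark.parametrize("seed", range(1, 6))
def test_rules_match_oracles_on_generated_genes(seed):
    """For genes with <= 8 transcripts each rule equals exhaustive brute force."""
    spec = FixtureSpec(
        seed=seed, n_genes=40, redundancy_rates=RedundancyRates.uniform(1.0)
    )
    w = generate_world(spec)
    merged = _merged_pre_dedup(w)
    for gid in merged.genes:
        g = merged.genes[gid]
        if g.n_transcripts > 8:
            continue
        txs = list(g.transcripts)
        got, _ = collapse_identical_chains(g)
        assert {t.transcript_id for t in got.transcripts} == _oracle_chain_collapse(txs)
        got, _ = collapse_monoexon(g)
        assert {t.transcript_id for t in got.transcripts} == _oracle_monoexon(txs)
        got, _ = remove_fragments(g)
        assert {t.transcript_id for t in got.transcripts} == _oracle_fragments(txs)


def _merged_pre_dedup(w):
    from rtdkit import apply_resolutions, pair_genes

    return apply_resolutions(w.ref, w.alt, pair_genes(w.ref, w.alt))


# --- merge_curated ---------------------------------------------------------


def _curated(*txs):
    return aset(list(txs), label="curated")


def test_merge_curated_empty_is_identity(small_world):
    out, dec = merge_curated(small_world.truth, AnnotationSet(source_label="curated"))
    assert out == small_world.truth and not dec


def test_curated_displaces_same_chain_shorter():
    existing = aset([tx("old", "g", [(10, 100), (201, 290)], source="ref")], "ref")
    cur = _curated(tx("new", "g", [(1, 100), (201, 300)], source="curated"))
    out, dec = merge_curated(existing, cur)
    assert out.transcript_ids() == {"new"}
    assert dec == [_d("old", "new", Rule.SAME_CHAIN_SHORTER_UTR)]


def test_curated_survives_even_when_shorter():
    existing = aset([tx("old", "g", [(1, 100), (201, 300)], source="ref")], "ref")
    cur = _curated(tx("new", "g", [(10, 100), (201, 290)], source="curated"))
    out, dec = merge_curated(existing, cur)
    assert "new" in out.transcript_ids()


def test_curated_new_gene_increments_gene_count(small_world):
    cur = _curated(tx("nt", "brand_new_gene", [(1, 100), (201, 300)], source="curated"))
    out, _ = merge_curated(small_world.truth, cur)
    assert out.n_genes == small_world.truth.n_genes + 1


def test_curated_id_collision_different_structure_conflicts():
    existing = aset([tx("t1", "g", [(1, 100)], source="ref")], "ref")
    cur = _curated(tx("t1", "g", [(1, 100), (201, 300)], source="curated"))
    with pytest.raises(ConflictError):
        merge_curated(existing, cur)


def test_rerunning_dedup_keeps_curated(small_world):
    # place the curated transcript inside the gene's span to keep the model valid
    gid = sorted(small_world.truth.genes)[0]
    span = small_world.truth.genes[gid].span
    cur = _curated(
        tx("c1", gid, [(span.start, span.start + 50), (span.start + 151, span.end)],
           strand=span.strand, source="curated")
    )
    cfg = DedupConfig(curated_labels=frozenset({"curated"}))
    out, _ = merge_curated(small_world.truth, cur, cfg)
    from rtdkit.dedup import dedup_gene

    g2, dec = dedup_gene(out.genes[gid], cfg)
    assert "c1" in {t.transcript_id for t in g2.transcripts}


# --- build_rtd -------------------------------------------------------------


def test_build_rtd_empty_inputs(empty_set):
    out, dec = build_rtd(empty_set, AnnotationSet(source_label="alt"))
    assert out.n_genes == 0 and not dec


def test_build_rtd_recovers_ground_truth():
    spec = FixtureSpec(seed=7, n_genes=60, redundancy_rates=RedundancyRates.uniform(0.7))
    ref, alt, truth, ledger = generate_annotation_pair(spec)
    out, dec = build_rtd(ref, alt)
    assert out == truth
    assert sorted((d.removed_transcript_id, d.rule) for d in dec) == sorted(
        (t.removed_id, t.rule) for t in ledger
    )


def test_build_rtd_idempotent(small_world, empty_set):
    out, _ = build_rtd(small_world.ref, small_world.alt)
    out2, dec2 = build_rtd(out, empty_set)
    assert not dec2 and out2 == out


def test_dedup_monotonic_and_gene_preserving(small_world):
    merged = _merged_pre_dedup(small_world)
    out, _ = build_rtd(small_world.ref, small_world.alt)
    assert out.n_transcripts <= merged.n_transcripts
    assert set(out.genes) == set(merged.genes)


def test_unique_nonfragment_chains_never_removed(small_world):
    """Safety: a transcript with a unique chain that is no fragment survives."""
    merged = _merged_pre_dedup(small_world)
    out, _ = build_rtd(small_world.ref, small_world.alt)
    surviving = out.transcript_ids()
    for g in merged.genes.values():
        chains = {}
        for t in g.transcripts:
            chains.setdefault(t.intron_chain().introns, []).append(t)
        for chain, members in chains.items():
            if len(members) > 1 or not chain:
                continue
            (t,) = members
            frag_of_any = any(
                u.spliced_length > t.spliced_length and is_fragment(t, u)
                for u in g.transcripts
                if u.transcript_id != t.transcript_id
            )
            if not frag_of_any:
                assert t.transcript_id in surviving
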