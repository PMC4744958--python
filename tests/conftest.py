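import pytest

from rtdkit import (
    AnnotationSet,
    FixtureSpec,
    GenomicInterval,
    TranscriptModel,
    generate_world,
)


def iv(start, end, chrom="Chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def tx(tid, gid, exons, strand="+", source="", chrom="Chr1"):
    """Build a transcript from (start, end) pairs."""
    return TranscriptModel(
        tid, gid, tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        source=source,
    )


def aset(transcripts, label="test", spans=None):
    return AnnotationSet.from_transcripts(transcripts, source_label=label, gene_spans=spans)


@pytest.fixture(scope="session")
def small_world():
    """A moderately sized synthetic world shared across read-only tests."""
    return generate_world(FixtureSpec(seed=11, n_genes=40))


@pytest.fixture()
def empty_set():
    return AnnotationSet(source_label="empty")
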