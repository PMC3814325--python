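import pytest

from clip_splicemap.models import (
    AltEvent,
    ClipTag,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)


def iv(chrom, start, end, strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def tag(chrom, start, end, strand="+", library="clip", tag_id="t"):
    return ClipTag(iv(chrom, start, end, strand), library=library, tag_id=tag_id)


@pytest.fixture
def toy_cassette_event():
    """Plus-strand cassette exon [1000,1100) with the spec's toy geometry:
    flanking exons [700,800) and [1400,1500), introns [800,1000) and
    [1100,1400)."""
    return AltEvent(
        event_id="ev1",
        category="cassette_exon",
        event_interval=iv("chr1", 1000, 1100),
        upstream_exon=iv("chr1", 700, 800),
        downstream_exon=iv("chr1", 1400, 1500),
        upstream_intron=iv("chr1", 800, 1000),
        downstream_intron=iv("chr1", 1100, 1400),
        host_gene="g1",
        flanking_constitutive=True,
    )


@pytest.fixture
def toy_minus_event():
    """Minus-strand cassette event; upstream (transcript 5') components lie
    at higher genomic coordinates."""
    return AltEvent(
        event_id="ev_minus",
        category="cassette_exon",
        event_interval=iv("chr2", 1000, 1100, "-"),
        upstream_exon=iv("chr2", 1400, 1500, "-"),
        downstream_exon=iv("chr2", 700, 800, "-"),
        upstream_intron=iv("chr2", 1100, 1400, "-"),
        downstream_intron=iv("chr2", 800, 1000, "-"),
        host_gene="g2",
        flanking_constitutive=True,
    )


@pytest.fixture
def two_exon_coding_gene():
    """Coding gene with two exons [100,200) and [300,420); CDS covers
    transcript coordinates [50, 170) (hand-summed across the junction)."""
    t = TranscriptModel(
        transcript_id="t1",
        gene_id="g1",
        exons=(iv("chr1", 100, 200), iv("chr1", 300, 420)),
        cds_start=50,
        cds_end=170,
        exon_roles=("constitutive", "constitutive"),
    )
    return GeneModel("g1", (t,))
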