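"""Core genomic domain types shared by every pipeline stage.

Coordinates are 0-based half-open (BED convention) throughout the package;
GTF input/output converts at the boundary. All overlap logic is strand-aware:
CLIP is a stranded protocol, so a tag never counts toward a feature on the
opposite strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

STRANDS = ("+", "-")

ALT_CATEGORIES = (
    "cassette_exon",
    "retained_intron",
    "alt_5ss",
    "alt_3ss",
    "alt_promoter",
    "alt_terminator",
)

#: Anchor names for splicing-map profiles, in the concatenation order used
#: for side-by-side reporting (transcript 5' -> 3' across the event).
ANCHORS = (
    "upstream_exon_5ss",
    "cassette_3ss",
    "cassette_5ss",
    "downstream_exon_3ss",
)

EXON_ROLES = ("constitutive", "cassette", "other")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True, slots=True)
class ClipTag:
    """A single mapped CLIP tag from either the CLIP or the control library."""

    interval: GenomicInterval
    library: str = "clip"
    tag_id: str = ""

    def __post_init__(self) -> None:
        if self.library not in ("clip", "control"):
            raise ValueError(f"unknown library {self.library!r}")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: exons in genomic order plus a CDS in transcript coordinates.

    ``cds_start``/``cds_end`` are nucleotide offsets from the transcript 5'
    end (``None`` for non-coding transcripts). ``exon_roles`` parallels
    ``exons`` and flags each exon as constitutive / cassette / other.
    ``skipped_exon_length`` is provenance set by
    :func:`clip_splicemap.quantify.skip_exon` so that frameshift status of a
    skip isoform can be reported; it is ``None`` for annotated transcripts.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    exon_roles: tuple[str, ...] = ()
    skipped_exon_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span several "
                "chromosomes or strands"
            )
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        object.__setattr__(self, "exons", tuple(ordered))
        if not self.exon_roles:
            object.__setattr__(
                self, "exon_roles", tuple("other" for _ in self.exons)
            )
        if len(self.exon_roles) != len(self.exons):
            raise ValueError(
                f"transcript {self.transcript_id}: exon_roles length mismatch"
            )
        for role in self.exon_roles:
            if role not in EXON_ROLES:
                raise ValueError(f"unknown exon role {role!r}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(
                f"transcript {self.transcript_id}: cds_start and cds_end "
                "must be given together"
            )
        if self.cds_start is not None:
            if not 0 <= self.cds_start < self.cds_end <= self.length:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS "
                    f"[{self.cds_start},{self.cds_end}) outside transcript "
                    f"of length {self.length}"
                )

    # -- derived geometry -------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    def exons_transcript_order(self) -> tuple[GenomicInterval, ...]:
        """Exons ordered 5'->3' along the transcript (strand-dependent)."""
        if self.strand == "+":
            return self.exons
        return tuple(reversed(self.exons))

    def exon_lengths_transcript_order(self) -> tuple[int, ...]:
        return tuple(len(e) for e in self.exons_transcript_order())

    def junctions(self) -> tuple[int, ...]:
        """Transcript coordinates of exon-exon junctions (5'->3')."""
        out, pos = [], 0
        lengths = self.exon_lengths_transcript_order()
        for ln in lengths[:-1]:
            pos += ln
            out.append(pos)
        return tuple(out)

    @property
    def last_junction(self) -> int:
        """Transcript coordinate of the final exon-exon junction."""
        if len(self.exons) < 2:
            raise ValueError("single-exon transcript has no junction")
        return self.junctions()[-1]

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts and an expression flag.

    The ``expressed`` flag stands in for an RNA-seq-derived expressed-gene
    filter: randomized controls (splicing-map control sets, permutation
    nulls) draw only from expressed genes.
    """

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    expressed: bool = True

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"gene {self.gene_id}: mixed chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


def _abuts(left: GenomicInterval, right: GenomicInterval) -> bool:
    return left.end == right.start


@dataclass(frozen=True)
class AltEvent:
    """An alternative-splicing event with its immediate flanking context.

    ``upstream``/``downstream`` are in transcript orientation. The flanking
    introns are optional: a retained-intron event *is* the intron, so its
    exons abut the event directly. All present components must abut without
    gaps and share chromosome and strand.
    """

    event_id: str
    category: str
    event_interval: GenomicInterval
    upstream_exon: GenomicInterval
    downstream_exon: GenomicInterval
    upstream_intron: Optional[GenomicInterval] = None
    downstream_intron: Optional[GenomicInterval] = None
    host_gene: str = ""
    flanking_constitutive: bool = False

    def __post_init__(self) -> None:
        if self.category not in ALT_CATEGORIES:
            raise ValueError(
                f"event {self.event_id}: unknown category {self.category!r}"
            )
        parts = [
            p
            for p in (
                self.upstream_exon,
                self.upstream_intron,
                self.event_interval,
                self.downstream_intron,
                self.downstream_exon,
            )
            if p is not None
        ]
        chroms = {p.chrom for p in parts}
        strands = {p.strand for p in parts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"event {self.event_id}: mixed chrom/strand")
        # In genomic coordinates the transcript-oriented chain runs left to
        # right on '+' and right to left on '-'.
        chain = parts if self.strand == "+" else list(reversed(parts))
        for a, b in zip(chain, chain[1:]):
            if not _abuts(a, b):
                raise ValueError(
                    f"event {self.event_id}: components do not abut "
                    f"({a.start}-{a.end} vs {b.start}-{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.event_interval.chrom

    @property
    def strand(self) -> str:
        return self.event_interval.strand


@dataclass(frozen=True)
class ClipCluster:
    """A merged site of overlapping CLIP tags with enrichment statistics."""

    cluster_id: str
    interval: GenomicInterval
    clip_count: int
    control_count: int
    peak_depth: int
    fold_enrichment: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if self.clip_count < 1:
            raise ValueError("a cluster must contain at least one CLIP tag")
        if self.control_count < 0 or self.peak_depth < 1:
            raise ValueError("invalid cluster counts")
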