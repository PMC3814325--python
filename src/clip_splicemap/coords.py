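"""Transcript <-> genomic coordinate arithmetic.

Transcript coordinates count nucleotides from the transcript 5' end, so on
minus-strand transcripts they run against genomic coordinates. These helpers
are the single place where that flip happens.
"""

from __future__ import annotations

from .models import GenomicInterval, TranscriptModel


def transcript_to_genomic_segments(
    transcript: TranscriptModel, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate window to genomic segments.

    Returns ``(start, end)`` pairs (0-based half-open, genomic order within
    each segment) covering exactly the transcript window ``[t_start, t_end)``.
    """
    if not 0 <= t_start < t_end <= transcript.length:
        raise ValueError(
            f"transcript window [{t_start},{t_end}) outside transcript "
            f"{transcript.transcript_id} of length {transcript.length}"
        )
    segments: list[tuple[int, int]] = []
    pos = 0
    for exon in transcript.exons_transcript_order():
        t0, t1 = pos, pos + len(exon)
        lo, hi = max(t_start, t0), min(t_end, t1)
        if lo < hi:
            if transcript.strand == "+":
                segments.append((exon.start + (lo - t0), exon.start + (hi - t0)))
            else:
                segments.append((exon.end - (hi - t0), exon.end - (lo - t0)))
        pos = t1
    return segments


def genomic_to_transcript(transcript: TranscriptModel, genomic_base: int) -> int:
    """Transcript coordinate of a genomic base; the base must be exonic."""
    pos = 0
    for exon in transcript.exons_transcript_order():
        if exon.start <= genomic_base < exon.end:
            if transcript.strand == "+":
                return pos + (genomic_base - exon.start)
            return pos + (exon.end - 1 - genomic_base)
        pos += len(exon)
    raise ValueError(
        f"genomic base {genomic_base} is not exonic in "
        f"{transcript.transcript_id}"
    )


def cds_genomic_segments(transcript: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic segments of the CDS of a coding transcript."""
    if not transcript.coding:
        raise ValueError(
            f"transcript {transcript.transcript_id} is non-coding"
        )
    return transcript_to_genomic_segments(
        transcript, transcript.cds_start, transcript.cds_end
    )
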