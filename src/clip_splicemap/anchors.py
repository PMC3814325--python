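"""Splice-site anchors of alternative-splicing events.

An anchor is an exon boundary of the event (in transcript orientation):
the 5' splice site of the upstream flanking exon, the 3' and 5' splice
sites of the alternative exon, and the 3' splice site of the downstream
flanking exon. Offsets from an anchor are transcript-oriented: positive
offsets run toward the transcript 3' end, so on minus-strand genes they
run toward decreasing genomic coordinates.

Offset 0 is the first base on the 3' side of the boundary (the first
intronic base of a 5' splice site; the first exonic base of a 3' splice
site); offset -1 is the first base on the 5' side.
"""

from __future__ import annotations

import numpy as np

from .models import ANCHORS, AltEvent


def anchor_boundary(event: AltEvent, anchor: str) -> int:
    """Genomic boundary coordinate (half-open convention) of an anchor."""
    if anchor not in ANCHORS:
        raise ValueError(f"unknown anchor {anchor!r}")
    plus = event.strand == "+"
    if anchor == "upstream_exon_5ss":
        return event.upstream_exon.end if plus else event.upstream_exon.start
    if anchor == "cassette_3ss":
        return event.event_interval.start if plus else event.event_interval.end
    if anchor == "cassette_5ss":
        return event.event_interval.end if plus else event.event_interval.start
    return event.downstream_exon.start if plus else event.downstream_exon.end


def offset_to_base(boundary: int, strand: str, offset: int) -> int:
    """Genomic base position at a transcript-oriented offset from a boundary."""
    if strand == "+":
        return boundary + offset
    return boundary - 1 - offset


def offsets_to_bases(boundary: int, strand: str, offsets: np.ndarray) -> np.ndarray:
    if strand == "+":
        return boundary + offsets
    return boundary - 1 - offsets
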