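"""Splicing quantification and AS-NMD prediction.

Gel-assay arithmetic (exon-skipping ratio from band intensities, per-isoform
reduction relative to mock transfection, 2^-ddCt relative expression) and
the nonsense-mediated-decay predictor for exon-skip isoforms.

NMD substrate status follows the canonical 50-nt exon-junction rule: a stop
codon whose first base lies more than 50 nt upstream of the last exon-exon
junction marks the transcript for degradation. The threshold is a
parameter; 50 is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

from .models import TranscriptModel

STOP_CODONS = frozenset({"UAA", "UAG", "UGA", "TAA", "TAG", "TGA"})

#: Default minimal PTC-to-last-junction distance for an NMD call (nt).
NMD_JUNCTION_RULE_NT = 50


# ---------------------------------------------------------------------------
# Band-intensity formulas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandPair:
    """Intensities of the exon-skipped and exon-included gel bands."""

    skipped_intensity: float
    included_intensity: float

    def __post_init__(self) -> None:
        if self.skipped_intensity < 0 or self.included_intensity < 0:
            raise ValueError("band intensities must be non-negative")
        if self.skipped_intensity == 0 and self.included_intensity == 0:
            raise ValueError("both band intensities are zero")


@dataclass(frozen=True)
class SkippingResult:
    skipping_ratio: float

    @property
    def inclusion_ratio(self) -> float:
        return 1.0 - self.skipping_ratio


def skipping_ratio(band_pair: BandPair) -> SkippingResult:
    """Exon-skipping ratio: skipped / (skipped + included)."""
    total = band_pair.skipped_intensity + band_pair.included_intensity
    return SkippingResult(band_pair.skipped_intensity / total)


@dataclass(frozen=True)
class IsoformReduction:
    isoform: str
    treated: float
    mock: float

    def __post_init__(self) -> None:
        if self.isoform not in ("included", "skipped"):
            raise ValueError(f"unknown isoform {self.isoform!r}")
        if self.mock <= 0:
            raise ValueError("mock intensity must be positive")
        if self.treated < 0:
            raise ValueError("treated intensity must be non-negative")

    @property
    def fraction_of_mock(self) -> float:
        return self.treated / self.mock


def reduction_relative_to_mock(
    treated: float, mock: float, isoform: str = "included"
) -> IsoformReduction:
    """Isoform level after treatment as a fraction of the mock transfection."""
    return IsoformReduction(isoform=isoform, treated=treated, mock=mock)


def ddct_relative_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method against a reference gene."""
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# Exon skipping and NMD prediction
# ---------------------------------------------------------------------------


def skip_exon(
    transcript: TranscriptModel,
    exon_index: int,
    sequence: Optional[str] = None,
) -> Tuple[TranscriptModel, Optional[str]]:
    """Remove one internal exon and re-splice, preserving the start codon.

    ``exon_index`` is 0-based in transcript order (exon 7 of a transcript is
    index 6). The removed exon must be internal and lie entirely downstream
    of the start codon; downstream transcript coordinates (including
    ``cds_end``) shift by the exon length. If ``sequence`` (the spliced
    transcript sequence) is given, the re-spliced sequence is returned
    alongside the model.
    """
    n = len(transcript.exons)
    if n < 3:
        raise ValueError("need at least 3 exons to skip an internal one")
    if not 0 < exon_index < n - 1:
        raise ValueError(
            f"exon_index {exon_index} is not internal (transcript has {n} exons)"
        )
    lengths = transcript.exon_lengths_transcript_order()
    seg_start = sum(lengths[:exon_index])
    seg_len = lengths[exon_index]
    seg_end = seg_start + seg_len

    cds_start = transcript.cds_start
    cds_end = transcript.cds_end
    if cds_start is not None:
        if cds_start >= seg_start:
            raise ValueError(
                "start codon is not upstream of the removed exon"
            )
        # Deletion mapping for the annotated stop.
        if cds_end >= seg_end:
            cds_end = cds_end - seg_len
        elif cds_end > seg_start:
            cds_end = seg_start
        if cds_end - cds_start < 3:
            raise ValueError("skipping leaves no room for a stop codon")

    exons_t = list(transcript.exons_transcript_order())
    roles_t = (
        list(transcript.exon_roles)
        if transcript.strand == "+"
        else list(reversed(transcript.exon_roles))
    )
    del exons_t[exon_index]
    del roles_t[exon_index]
    if transcript.strand == "-":
        exons_t = list(reversed(exons_t))
        roles_t = list(reversed(roles_t))

    model = TranscriptModel(
        transcript_id=f"{transcript.transcript_id}.skip{exon_index + 1}",
        gene_id=transcript.gene_id,
        exons=tuple(exons_t),
        cds_start=cds_start,
        cds_end=cds_end,
        exon_roles=tuple(roles_t),
        skipped_exon_length=seg_len,
    )
    new_seq = None
    if sequence is not None:
        if len(sequence) != transcript.length:
            raise ValueError("sequence length does not match the transcript")
        new_seq = sequence[:seg_start] + sequence[seg_end:]
    return model, new_seq


@dataclass(frozen=True)
class NmdCall:
    """AS-NMD prediction for one transcript isoform.

    ``frameshift`` is ``None`` (not applicable) for transcripts that were
    not produced by :func:`skip_exon`. ``ptc_position`` is the transcript
    coordinate of the first base of the premature stop codon, or ``None``
    if translation reaches the annotated stop (or no stop at all, flagged
    by ``no_stop``).
    """

    frameshift: Optional[bool]
    ptc_position: Optional[int]
    last_junction_position: int
    ptc_to_last_junction: Optional[int]
    nmd: bool
    no_stop: bool = False


def _first_stop(sequence: str, cds_start: int) -> Optional[int]:
    """Transcript coordinate of the first in-frame stop codon, scanning
    from the start codon to the end of the sequence."""
    seq = sequence.upper()
    for pos in range(cds_start, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def predict_nmd(
    transcript: TranscriptModel,
    transcript_sequence: str,
    junction_rule_nt: int = NMD_JUNCTION_RULE_NT,
) -> NmdCall:
    """Predict NMD substrate status of a (possibly exon-skipped) transcript.

    Translation starts at ``cds_start`` and runs to the first stop codon.
    A premature termination codon (PTC) exists when that stop precedes the
    annotated one; the transcript is an NMD substrate when the PTC's first
    base lies more than ``junction_rule_nt`` nucleotides upstream of the
    last exon-exon junction.
    """
    if not transcript.coding:
        raise ValueError(
            f"transcript {transcript.transcript_id} is non-coding; "
            "NMD prediction needs a CDS"
        )
    if len(transcript_sequence) != transcript.length:
        raise ValueError(
            f"sequence length {len(transcript_sequence)} does not match "
            f"transcript length {transcript.length}"
        )
    frameshift: Optional[bool] = None
    if transcript.skipped_exon_length is not None:
        frameshift = transcript.skipped_exon_length % 3 != 0

    last_junction = transcript.last_junction
    annotated_stop = transcript.cds_end - 3
    first_stop = _first_stop(transcript_sequence, transcript.cds_start)

    if first_stop is None:
        return NmdCall(
            frameshift=frameshift,
            ptc_position=None,
            last_junction_position=last_junction,
            ptc_to_last_junction=None,
            nmd=False,
            no_stop=True,
        )
    ptc = first_stop if first_stop < annotated_stop else None
    distance = last_junction - ptc if ptc is not None else None
    nmd = ptc is not None and distance > junction_rule_nt
    return NmdCall(
        frameshift=frameshift,
        ptc_position=ptc,
        last_junction_position=last_junction,
        ptc_to_last_junction=distance,
        nmd=nmd,
    )
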