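"""Normalized complexity maps of tag binding around cassette exons.

The splicing map answers "at which offsets from the splice sites of
regulated exons does the protein sit?". For each event and each
transcript-oriented offset d in [-window, +window] from an anchor boundary,
an indicator records whether at least one same-strand tag covers the base
at that offset; the profile value at d is the fraction of events with a
covering tag. Each event therefore contributes at most 1 at each offset
regardless of its tag count — per-event saturation is the normalization
that puts deep and shallow events on a common 0-1 axis.

The control is an average over random sets of constitutive exons from
expressed genes, profiled at their own 3' and 5' splice sites, mirroring
the cassette anchors. The exceedance at each offset standardizes the
observed-minus-control difference on the arcsine-square-root scale:

    z(d) = (T(value) - mean_sets T(set)) /
           (sd_sets T(set) * sqrt(1 + set_size / n_events)),   T(v) = asin(sqrt(v))

The transform stabilizes the variance of binomial proportions, removing
the heavy upper tail that raw fractions have where coverage is sparse; the
sqrt(1 + set_size/n_events) factor is the null standard deviation of a
difference between two independent set-level profiles (the observed event
set and one control set), a deliberately conservative standardization given
the thousands of offsets scanned per map. Peaks are contiguous excursions
of the smoothed exceedance above a z threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._index import StrandedIntervalArrays
from .anchors import anchor_boundary, offsets_to_bases
from .errors import DataError
from .models import ANCHORS, AltEvent, ClipTag, GeneModel

DEFAULT_WINDOW = 500

#: Which control boundary (3' or 5' splice site) mirrors each map anchor.
ANCHOR_BOUNDARY_KIND = {
    "upstream_exon_5ss": "5ss",
    "cassette_3ss": "3ss",
    "cassette_5ss": "5ss",
    "downstream_exon_3ss": "3ss",
}


@dataclass(frozen=True)
class ComplexityProfile:
    """Per-offset fraction of events with >=1 covering tag at one anchor."""

    anchor: str
    offsets: np.ndarray
    values: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("profile values must lie in [0, 1]")


@dataclass(frozen=True)
class ControlProfile:
    """Random constitutive-exon control: per-set profiles at both splice sites.

    ``sets`` maps boundary kind ("3ss"/"5ss") to an (n_sets, n_offsets)
    matrix of per-set normalized complexity values."""

    offsets: np.ndarray
    sets: dict[str, np.ndarray]
    n_sets: int
    set_size: int

    def mean(self, anchor: str) -> np.ndarray:
        return self.sets[ANCHOR_BOUNDARY_KIND[anchor]].mean(axis=0)

    def sd(self, anchor: str) -> np.ndarray:
        if self.n_sets < 2:
            raise ValueError("need n_sets >= 2 for a control sd")
        return self.sets[ANCHOR_BOUNDARY_KIND[anchor]].std(axis=0, ddof=1)


@dataclass(frozen=True)
class MapPeak:
    anchor: str
    offset: int
    value: float
    control_mean: float
    control_sd: float
    exceedance: float


# ---------------------------------------------------------------------------
# Indicators and profiles
# ---------------------------------------------------------------------------


def _indicator_matrix(
    index: StrandedIntervalArrays,
    anchors: Sequence[tuple[str, str, int]],
    window: int,
) -> np.ndarray:
    """(n_anchors, 2*window+1) binary matrix of per-offset tag coverage."""
    offsets = np.arange(-window, window + 1)
    out = np.zeros((len(anchors), offsets.size), dtype=np.int8)
    for i, (chrom, strand, boundary) in enumerate(anchors):
        positions = offsets_to_bases(boundary, strand, offsets)
        cov = index.coverage_at(chrom, strand, positions)
        out[i] = cov > 0
    return out


def event_coverage_indicator(
    tags: Sequence[ClipTag],
    event: AltEvent,
    anchor: str,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Binary coverage indicator over offsets -window..window for one event.

    indicator[d] is 1 iff at least one same-strand tag covers the base at
    transcript-oriented offset d from the anchor boundary."""
    index = StrandedIntervalArrays(t.interval for t in tags)
    boundary = anchor_boundary(event, anchor)
    return _indicator_matrix(
        index, [(event.chrom, event.strand, boundary)], window
    )[0]


def normalized_complexity(
    tags: Sequence[ClipTag],
    events: Sequence[AltEvent],
    anchor: str,
    window: int = DEFAULT_WINDOW,
) -> ComplexityProfile:
    """Fraction of events with a covering tag, per offset from the anchor."""
    if not events:
        raise DataError("normalized complexity needs at least one event")
    index = StrandedIntervalArrays(t.interval for t in tags)
    anchors = [
        (ev.chrom, ev.strand, anchor_boundary(ev, anchor)) for ev in events
    ]
    matrix = _indicator_matrix(index, anchors, window)
    return ComplexityProfile(
        anchor=anchor,
        offsets=np.arange(-window, window + 1),
        values=matrix.mean(axis=0),
        n_events=len(events),
    )


def _internal_constitutive_exons(gene_models: Sequence[GeneModel]):
    """(chrom, strand, 3ss boundary, 5ss boundary) per internal constitutive
    exon of expressed genes; internal exons have both splice sites."""
    out = []
    for gene in gene_models:
        if not gene.expressed:
            continue
        for t in gene.transcripts:
            exons_t = t.exons_transcript_order()
            for i in range(1, len(exons_t) - 1):
                role = (
                    t.exon_roles[i]
                    if t.strand == "+"
                    else t.exon_roles[len(exons_t) - 1 - i]
                )
                if role != "constitutive":
                    continue
                exon = exons_t[i]
                if t.strand == "+":
                    out.append((t.chrom, t.strand, exon.start, exon.end))
                else:
                    out.append((t.chrom, t.strand, exon.end, exon.start))
    return out


def control_profile(
    tags: Sequence[ClipTag],
    gene_models: Sequence[GeneModel],
    set_size: int,
    n_sets: int = 100,
    window: int = DEFAULT_WINDOW,
    seed: int = 0,
) -> ControlProfile:
    """Average normalized complexity of random constitutive-exon sets.

    Each set samples ``set_size`` internal constitutive exons (without
    replacement within a set, independently across sets) from expressed
    genes and profiles them at their own 3' and 5' splice sites."""
    exon_anchors = _internal_constitutive_exons(gene_models)
    if len(exon_anchors) < set_size:
        raise DataError(
            f"only {len(exon_anchors)} internal constitutive exons available "
            f"for control sets of size {set_size}"
        )
    index = StrandedIntervalArrays(t.interval for t in tags)
    # Indicators are computed once per distinct exon; sets then average rows.
    m3 = _indicator_matrix(
        index, [(c, s, b3) for c, s, b3, _ in exon_anchors], window
    ).astype(float)
    m5 = _indicator_matrix(
        index, [(c, s, b5) for c, s, _, b5 in exon_anchors], window
    ).astype(float)
    rng = np.random.default_rng(seed)
    sets3 = np.empty((n_sets, 2 * window + 1))
    sets5 = np.empty((n_sets, 2 * window + 1))
    for s in range(n_sets):
        pick = rng.choice(len(exon_anchors), size=set_size, replace=False)
        sets3[s] = m3[pick].mean(axis=0)
        sets5[s] = m5[pick].mean(axis=0)
    return ControlProfile(
        offsets=np.arange(-window, window + 1),
        sets={"3ss": sets3, "5ss": sets5},
        n_sets=n_sets,
        set_size=set_size,
    )


# ---------------------------------------------------------------------------
# Peak calling on the map
# ---------------------------------------------------------------------------


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; edges divide by the in-window count."""
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _asin_sqrt(v: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt(np.clip(v, 0.0, 1.0)))


def exceedance_profile(
    profile: ComplexityProfile,
    control: ControlProfile,
    smoothing: int = 11,
    sd_floor: Optional[float] = None,
):
    """Smoothed value, raw-scale control mean/sd, and exceedance arrays.

    Returned value/control arrays are on the raw (fraction) scale for
    interpretability; the exceedance is computed on the arcsine-square-root
    scale as described in the module docstring. Smoothing is applied to
    each control set before taking the across-set sd, so the exceedance
    stays correctly standardized after smoothing; the sd is floored at
    ``1/(2*set_size)`` (roughly half a count on the transformed scale) to
    avoid division blow-ups in tag-free stretches."""
    window = (profile.offsets.size - 1) // 2
    if smoothing % 2 == 0 or smoothing < 1:
        raise ValueError("smoothing width must be a positive odd integer")
    if smoothing > window:
        raise ValueError("smoothing width exceeds the profile window")
    if control.n_sets < 2:
        raise ValueError("need n_sets >= 2 to standardize exceedance")
    values = profile.values.astype(float)
    set_matrix = control.sets[ANCHOR_BOUNDARY_KIND[profile.anchor]]
    sm_value = _smooth(values, smoothing)
    sm_mean = _smooth(set_matrix.mean(axis=0), smoothing)
    sm_sd = np.vstack([_smooth(row, smoothing) for row in set_matrix]).std(
        axis=0, ddof=1
    )
    # Standardization on the variance-stabilized scale.
    t_value = _smooth(_asin_sqrt(values), smoothing)
    t_sets = np.vstack([_smooth(_asin_sqrt(row), smoothing) for row in set_matrix])
    t_mean = t_sets.mean(axis=0)
    t_sd = t_sets.std(axis=0, ddof=1)
    if sd_floor is None:
        sd_floor = 1.0 / (2.0 * control.set_size)
    sd_eff = np.maximum(t_sd, sd_floor)
    scale = np.sqrt(1.0 + control.set_size / profile.n_events)
    exceedance = (t_value - t_mean) / (sd_eff * scale)
    return sm_value, sm_mean, sm_sd, exceedance


def call_map_peaks(
    profile: ComplexityProfile,
    control: ControlProfile,
    smoothing: int = 11,
    z_threshold: float = 3.0,
) -> list[MapPeak]:
    """Peaks of the smoothed exceedance above the z threshold.

    Each maximal contiguous excursion above the threshold is reported once,
    at the exceedance-weighted centroid of the excursion (weights are the
    excess over the threshold). One physical binding site therefore yields
    one peak, located stably even when noise ripples the excursion top —
    the argmax of a noise-flattened excursion wanders by tens of
    nucleotides, the centroid does not.
    """
    sm_value, sm_mean, sm_sd, exceedance = exceedance_profile(
        profile, control, smoothing
    )
    above = exceedance >= z_threshold
    idx = []
    i, n = 0, above.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        weights = exceedance[i:j] - z_threshold + 1e-12
        centroid = float((np.arange(i, j) * weights).sum() / weights.sum())
        idx.append(int(round(centroid)))
        i = j
    return [
        MapPeak(
            anchor=profile.anchor,
            offset=int(profile.offsets[i]),
            value=float(sm_value[i]),
            control_mean=float(sm_mean[i]),
            control_sd=float(sm_sd[i]),
            exceedance=float(exceedance[i]),
        )
        for i in sorted(idx)
    ]


def profile_table(
    profiles: Sequence[ComplexityProfile],
    control: ControlProfile,
    smoothing: int = 11,
) -> pd.DataFrame:
    """Long-form table (anchor, offset, value, control stats, exceedance),
    anchors in map concatenation order."""
    frames = []
    order = {a: i for i, a in enumerate(ANCHORS)}
    for profile in sorted(profiles, key=lambda p: order[p.anchor]):
        sm_value, sm_mean, sm_sd, exceedance = exceedance_profile(
            profile, control, smoothing
        )
        frames.append(
            pd.DataFrame(
                {
                    "anchor": profile.anchor,
                    "offset": profile.offsets,
                    "value": profile.values,
                    "control_mean": sm_mean,
                    "control_sd": sm_sd,
                    "exceedance": exceedance,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
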