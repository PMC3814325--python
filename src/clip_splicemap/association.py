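"""Association of CLIP clusters with alternative-splicing events.

A cluster is scored as associated with an event if it overlaps the event
itself or its immediate flanking introns and/or exons on the same strand.
Observed per-category counts are compared with a permutation null in which
every cluster is relocated, preserving its length, to a uniformly random
position within the transcribed spans of expressed genes (taking the host
gene's strand); the comparison is summarized as a Z-score per category.

An event associated through several clusters counts once: the statistic is
the number of alternative events, not cluster-event pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._index import StrandedIntervalArrays
from .errors import DataError
from .models import ALT_CATEGORIES, AltEvent, ClipCluster, GeneModel, GenomicInterval


@dataclass(frozen=True)
class AssociationRecord:
    event_id: str
    category: str
    associated: bool
    supporting_cluster_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.associated != bool(self.supporting_cluster_ids):
            raise ValueError(
                "associated flag inconsistent with supporting clusters"
            )


@dataclass(frozen=True)
class CategoryEnrichment:
    """Observed vs permutation-expected association count for one category.

    ``z_score`` is ``None`` when the permutation standard deviation is zero
    or undefined (single trial)."""

    category: str
    observed: int
    expected_mean: float
    expected_sd: Optional[float]
    z_score: Optional[float]
    n_trials: int


def association_region(event: AltEvent) -> GenomicInterval:
    """Contiguous union of the event and its flanking introns and exons."""
    parts = [
        p
        for p in (
            event.upstream_exon,
            event.upstream_intron,
            event.event_interval,
            event.downstream_intron,
            event.downstream_exon,
        )
        if p is not None
    ]
    return GenomicInterval(
        event.chrom,
        min(p.start for p in parts),
        max(p.end for p in parts),
        event.strand,
    )


def associate(
    clusters: Sequence[ClipCluster], events: Sequence[AltEvent]
) -> list[AssociationRecord]:
    """Score every event against the cluster set (strand-aware overlap)."""
    # Bucket clusters per (chrom, strand), sorted by start, so supporting
    # ids can be recovered without quadratic scanning.
    buckets: dict[tuple[str, str], list[ClipCluster]] = {}
    for cl in clusters:
        buckets.setdefault((cl.interval.chrom, cl.interval.strand), []).append(cl)
    for key in buckets:
        buckets[key].sort(key=lambda c: c.interval.start)
    records = []
    for ev in events:
        region = association_region(ev)
        support = []
        for cl in buckets.get((region.chrom, region.strand), []):
            if cl.interval.start >= region.end:
                break
            if cl.interval.end > region.start:
                support.append(cl.cluster_id)
        records.append(
            AssociationRecord(
                event_id=ev.event_id,
                category=ev.category,
                associated=bool(support),
                supporting_cluster_ids=tuple(support),
            )
        )
    return records


def count_by_category(records: Sequence[AssociationRecord]) -> dict[str, int]:
    """Associated-event counts per category (every category present)."""
    counts = {cat: 0 for cat in ALT_CATEGORIES}
    for rec in records:
        if rec.associated:
            counts[rec.category] += 1
    return counts


def _count_associated_fast(
    cluster_index: StrandedIntervalArrays, regions: Sequence[GenomicInterval],
    categories: Sequence[str],
) -> dict[str, int]:
    counts = {cat: 0 for cat in ALT_CATEGORIES}
    for region, cat in zip(regions, categories):
        if cluster_index.count_overlapping(region) > 0:
            counts[cat] += 1
    return counts


@dataclass(frozen=True)
class PermutationNull:
    expected_mean: dict[str, float]
    expected_sd: dict[str, Optional[float]]
    n_trials: int
    seed: int


def permutation_null(
    clusters: Sequence[ClipCluster],
    events: Sequence[AltEvent],
    gene_models: Sequence[GeneModel],
    n_trials: int = 100,
    seed: int = 0,
) -> PermutationNull:
    """Per-category expected association counts under random relocation.

    Each trial relocates every cluster, preserving its length, to a
    uniformly random transcribed base among expressed genes (the cluster
    takes the host gene's strand and must fit inside its span). Means and
    sample (n-1) standard deviations are taken over trials; with a single
    trial the sd is undefined (``None``).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    expressed = [g for g in gene_models if g.expressed]
    if not expressed:
        raise DataError("no expressed genes for the permutation null")
    spans = [g.span for g in expressed]
    span_len = np.array([len(s) for s in spans], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(span_len)])
    total = int(cum[-1])
    lengths = np.array([len(c.interval) for c in clusters], dtype=np.int64)
    if lengths.size and lengths.max() > span_len.max():
        raise DataError(
            "a cluster is longer than every expressed gene span; it cannot "
            "be relocated"
        )
    regions = [association_region(ev) for ev in events]
    categories = [ev.category for ev in events]

    rng = np.random.default_rng(seed)
    per_trial = {cat: np.zeros(n_trials) for cat in ALT_CATEGORIES}
    n = lengths.size
    for trial in range(n_trials):
        starts = np.empty(n, dtype=np.int64)
        gidx = np.empty(n, dtype=np.int64)
        pending = np.arange(n)
        # Rejection sampling: redraw clusters that overhang their gene span.
        for _ in range(1000):
            if pending.size == 0:
                break
            u = rng.integers(0, total, size=pending.size)
            g = np.searchsorted(cum, u, side="right") - 1
            s = np.array([spans[i].start for i in g]) + (u - cum[g])
            ok = s + lengths[pending] <= np.array([spans[i].end for i in g])
            starts[pending[ok]] = s[ok]
            gidx[pending[ok]] = g[ok]
            pending = pending[~ok]
        else:
            raise DataError("cluster relocation failed to converge")
        relocated = [
            GenomicInterval(
                spans[gidx[i]].chrom,
                int(starts[i]),
                int(starts[i] + lengths[i]),
                spans[gidx[i]].strand,
            )
            for i in range(n)
        ]
        index = StrandedIntervalArrays(relocated)
        counts = _count_associated_fast(index, regions, categories)
        for cat in ALT_CATEGORIES:
            per_trial[cat][trial] = counts[cat]

    mean = {cat: float(per_trial[cat].mean()) for cat in ALT_CATEGORIES}
    if n_trials >= 2:
        sd = {cat: float(per_trial[cat].std(ddof=1)) for cat in ALT_CATEGORIES}
    else:
        sd = {cat: None for cat in ALT_CATEGORIES}
    return PermutationNull(
        expected_mean=mean, expected_sd=sd, n_trials=n_trials, seed=seed
    )


def z_scores(
    observed: dict[str, int], null: PermutationNull
) -> list[CategoryEnrichment]:
    """Z-scores per category; undefined (None) when the null sd is zero."""
    out = []
    for cat in ALT_CATEGORIES:
        obs = observed.get(cat, 0)
        mean = null.expected_mean[cat]
        sd = null.expected_sd[cat]
        z = None
        if sd is not None and sd > 0:
            z = (obs - mean) / sd
        out.append(
            CategoryEnrichment(
                category=cat,
                observed=obs,
                expected_mean=mean,
                expected_sd=sd,
                z_score=z,
                n_trials=null.n_trials,
            )
        )
    return out


def select_flanked_cassette_events(
    records: Sequence[AssociationRecord], events: Sequence[AltEvent]
) -> list[AltEvent]:
    """Associated cassette-exon events whose flanking exons are constitutive.

    This is the event subset the splicing map is computed on."""
    associated = {r.event_id for r in records if r.associated}
    return [
        ev
        for ev in events
        if ev.category == "cassette_exon"
        and ev.event_id in associated
        and ev.flanking_constitutive
    ]
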