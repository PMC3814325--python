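"""CLIP-cluster calling against a control library.

The pipeline's equivalent of a peak-finder step: deduplicate tags, chain
overlapping same-strand tags into candidate clusters, and score each
cluster's CLIP-vs-control enrichment with a conditional binomial test under
Benjamini-Hochberg FDR control.

The two-library model: given a cluster with ``c`` CLIP tags and ``k``
control tags overlapping its extent, and unique library sizes ``N_clip``
and ``N_ctrl``, the null hypothesis is that each of the ``c + k`` tags fell
in the CLIP library with probability ``pi = N_clip / (N_clip + N_ctrl)``
independently of position. The one-sided p-value is ``P(X >= c)`` for
``X ~ Binomial(c + k, pi)``; fold enrichment uses a 0.5 pseudocount on both
rates so it is finite at ``k = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from ._index import StrandedIntervalArrays
from .models import ClipCluster, ClipTag, GenomicInterval


@dataclass(frozen=True)
class LibraryStats:
    """Unique-tag counts of the two libraries, the test's normalizers."""

    n_clip_unique: int
    n_control_unique: int

    def __post_init__(self) -> None:
        if self.n_clip_unique <= 0 or self.n_control_unique <= 0:
            raise ValueError("library sizes must be positive for scoring")

    @property
    def pi(self) -> float:
        return self.n_clip_unique / (self.n_clip_unique + self.n_control_unique)


def deduplicate(tags: Sequence[ClipTag]) -> list[ClipTag]:
    """Drop tags sharing (chrom, start, end, strand), order-independently.

    The survivor of a duplicate group is the one with the smallest tag_id,
    so the result does not depend on input order. Idempotent.
    """
    best: dict[tuple[str, int, int, str], ClipTag] = {}
    for tag in tags:
        iv = tag.interval
        key = (iv.chrom, iv.start, iv.end, iv.strand)
        prev = best.get(key)
        if prev is None or tag.tag_id < prev.tag_id:
            best[key] = tag
    return [best[key] for key in sorted(best)]


def _chain_tags(starts: np.ndarray, ends: np.ndarray):
    """Chain start-sorted tags into clusters; >=1 shared base merges.

    Returns (cluster_id per tag, first-tag index per cluster,
    cluster end per cluster, peak base-level depth per cluster).
    """
    n = len(starts)
    run_max_end = np.maximum.accumulate(ends)
    prev_max = np.empty(n, dtype=np.int64)
    prev_max[0] = -1
    prev_max[1:] = run_max_end[:-1]
    # Half-open semantics: abutting tags (start == previous max end) do not
    # share a base and start a new cluster.
    is_new = starts >= prev_max
    cid = np.cumsum(is_new) - 1
    bounds = np.flatnonzero(is_new)
    cluster_end = np.maximum.reduceat(ends, bounds)

    # Peak depth by event sweep: +1 at each start, -1 at each end, ends
    # processed first on ties (half-open coverage).
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([np.ones(n, dtype=np.int64), -np.ones(n, dtype=np.int64)])
    order = np.lexsort((delta, pos))
    coverage = np.cumsum(delta[order])
    ev_cid = np.concatenate([cid, cid])[order]
    # Clusters are disjoint and position-ordered, so events arrive grouped.
    ev_bounds = np.searchsorted(ev_cid, np.arange(len(bounds)), side="left")
    peak_depth = np.maximum.reduceat(coverage, ev_bounds)
    return cid, bounds, cluster_end, peak_depth


def build_clusters(
    unique_tags: Sequence[ClipTag],
    min_depth: int = 2,
    control_tags: Optional[Sequence[ClipTag]] = None,
) -> list[ClipCluster]:
    """Merge overlapping same-strand tags into candidate clusters.

    A candidate's interval is the union of its member tags; ``clip_count``
    is the member count, ``peak_depth`` the maximum simultaneous base-level
    coverage. Candidates with ``peak_depth < min_depth`` are dropped.
    ``control_count`` counts control tags overlapping the final cluster
    extent on the same strand (the control library is a background
    estimator, not a peak set).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    control_index = (
        StrandedIntervalArrays(t.interval for t in control_tags)
        if control_tags
        else None
    )
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for tag in unique_tags:
        iv = tag.interval
        grouped.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))

    candidates: list[ClipCluster] = []
    for (chrom, strand), pairs in grouped.items():
        arr = np.asarray(pairs, dtype=np.int64)
        order = np.argsort(arr[:, 0], kind="stable")
        starts, ends = arr[order, 0], arr[order, 1]
        cid, bounds, cluster_end, peak_depth = _chain_tags(starts, ends)
        counts = np.diff(np.append(bounds, len(starts)))
        keep = peak_depth >= min_depth
        cl_start = starts[bounds]
        if control_index is not None:
            control_counts = control_index.count_overlapping_many(
                chrom, strand, cl_start, cluster_end
            )
        else:
            control_counts = np.zeros(len(bounds), dtype=np.int64)
        for j in np.flatnonzero(keep):
            candidates.append(
                ClipCluster(
                    cluster_id="",
                    interval=GenomicInterval(
                        chrom, int(cl_start[j]), int(cluster_end[j]), strand
                    ),
                    clip_count=int(counts[j]),
                    control_count=int(control_counts[j]),
                    peak_depth=int(peak_depth[j]),
                )
            )
    candidates.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.interval.strand))
    width = max(6, len(str(len(candidates))))
    return [
        ClipCluster(
            cluster_id=f"cl_{i + 1:0{width}d}",
            interval=c.interval,
            clip_count=c.clip_count,
            control_count=c.control_count,
            peak_depth=c.peak_depth,
        )
        for i, c in enumerate(candidates)
    ]


def score_cluster(
    clip_count: int, control_count: int, stats: LibraryStats
) -> tuple[float, float]:
    """Fold enrichment and one-sided binomial p for a single cluster."""
    if clip_count < 1:
        raise ValueError(
            "clusters are built from CLIP tags, so clip_count must be >= 1"
        )
    if control_count < 0:
        raise ValueError("control_count must be >= 0")
    fold, p = _score_arrays(
        np.array([clip_count]), np.array([control_count]), stats
    )
    return float(fold[0]), float(p[0])


def _score_arrays(
    clip_counts: np.ndarray, control_counts: np.ndarray, stats: LibraryStats
) -> tuple[np.ndarray, np.ndarray]:
    c = clip_counts.astype(np.int64)
    k = control_counts.astype(np.int64)
    fold = ((c + 0.5) / stats.n_clip_unique) / ((k + 0.5) / stats.n_control_unique)
    # P(X >= c) for X ~ Binomial(c + k, pi)
    p = sps.binom.sf(c - 1, c + k, stats.pi)
    return fold, np.minimum(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_clusters(
    clip_tags: Sequence[ClipTag],
    control_tags: Sequence[ClipTag],
    min_depth: int = 2,
    alpha: float = 0.05,
) -> list[ClipCluster]:
    """Full cluster-calling pass: dedup, chain, score, BH-adjust.

    Returns clusters sorted by (chrom, start); ``significant`` marks
    ``q <= alpha``.
    """
    if not clip_tags:
        raise DataError("CLIP library is empty")
    if not control_tags:
        raise DataError("control library is empty")
    clip_unique = deduplicate(clip_tags)
    control_unique = deduplicate(control_tags)
    stats = LibraryStats(len(clip_unique), len(control_unique))
    candidates = build_clusters(
        clip_unique, min_depth=min_depth, control_tags=control_unique
    )
    if not candidates:
        return []
    c = np.array([cl.clip_count for cl in candidates])
    k = np.array([cl.control_count for cl in candidates])
    fold, p = _score_arrays(c, k, stats)
    q = bh_fdr(p)
    return [
        ClipCluster(
            cluster_id=cl.cluster_id,
            interval=cl.interval,
            clip_count=cl.clip_count,
            control_count=cl.control_count,
            peak_depth=cl.peak_depth,
            fold_enrichment=float(fold[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            significant=bool(q[i] <= alpha),
        )
        for i, cl in enumerate(candidates)
    ]
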