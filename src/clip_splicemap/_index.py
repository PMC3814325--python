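"""Internal numpy-backed interval indexes.

Overlap and coverage counting over sorted start/end arrays, grouped by
(chromosome, strand). Counting rests on the identity

    #{intervals overlapping [s, e)} = #{start < e} - #{end <= s}

which holds for any set of half-open intervals (every interval with
``end <= s`` also has ``start < e``), so no nesting assumptions are needed.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .models import GenomicInterval

Key = tuple[str, str]


class StrandedIntervalArrays:
    """Per-(chrom, strand) sorted start and end arrays."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        grouped: dict[Key, list[tuple[int, int]]] = {}
        for iv in intervals:
            grouped.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
        self._starts: dict[Key, np.ndarray] = {}
        self._ends: dict[Key, np.ndarray] = {}
        for key, pairs in grouped.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._starts[key] = np.sort(arr[:, 0])
            self._ends[key] = np.sort(arr[:, 1])

    def keys(self) -> list[Key]:
        return list(self._starts)

    def count_overlapping(self, interval: GenomicInterval) -> int:
        key = (interval.chrom, interval.strand)
        if key not in self._starts:
            return 0
        n_start = np.searchsorted(self._starts[key], interval.end, side="left")
        n_ended = np.searchsorted(self._ends[key], interval.start, side="right")
        return int(n_start - n_ended)

    def count_overlapping_many(
        self, chrom: str, strand: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._starts:
            return np.zeros(len(starts), dtype=np.int64)
        n_start = np.searchsorted(self._starts[key], ends, side="left")
        n_ended = np.searchsorted(self._ends[key], starts, side="right")
        return n_start - n_ended

    def coverage_at(self, chrom: str, strand: str, positions: np.ndarray) -> np.ndarray:
        """Number of intervals covering each base position."""
        key = (chrom, strand)
        if key not in self._starts:
            return np.zeros(len(positions), dtype=np.int64)
        n_started = np.searchsorted(self._starts[key], positions, side="right")
        n_ended = np.searchsorted(self._ends[key], positions, side="right")
        return n_started - n_ended
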