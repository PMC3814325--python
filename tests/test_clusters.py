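"""Cluster calling: deduplication, chaining, the binomial score, and BH."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clip_splicemap.clusters import (
    LibraryStats,
    bh_fdr,
    build_clusters,
    call_clusters,
    deduplicate,
    score_cluster,
)
from clip_splicemap.errors import DataError

from conftest import tag


def exact_binom_tail(c: int, n: int, pi: Fraction) -> Fraction:
    """Independent oracle: P(X >= c) by exhaustive PMF summation."""
    return sum(
        Fraction(comb(n, x)) * pi**x * (1 - pi) ** (n - x) for x in range(c, n + 1)
    )


class TestDeduplicate:
    def test_distinct_input_unchanged(self):
        tags = [tag("chr1", i, i + 10, tag_id=f"t{i}") for i in range(5)]
        assert len(deduplicate(tags)) == 5

    def test_hand_counted_duplicates(self):
        tags = [tag("chr1", i, i + 10, tag_id=f"t{i}") for i in range(7)]
        tags += [
            tag("chr1", 0, 10, tag_id="d0"),
            tag("chr1", 1, 11, tag_id="d1"),
            tag("chr1", 2, 12, tag_id="d2"),
        ]
        assert len(deduplicate(tags)) == 7

    def test_order_independent_and_idempotent(self):
        tags = [tag("chr1", i % 4, i % 4 + 10, tag_id=f"t{i}") for i in range(12)]
        a = deduplicate(tags)
        b = deduplicate(list(reversed(tags)))
        assert [(t.interval, t.tag_id) for t in a] == [
            (t.interval, t.tag_id) for t in b
        ]
        assert deduplicate(a) == a

    def test_strand_distinguishes_tags(self):
        tags = [tag("chr1", 0, 10, "+"), tag("chr1", 0, 10, "-")]
        assert len(deduplicate(tags)) == 2


class TestBuildClusters:
    def test_overlap_chaining(self):
        clusters = build_clusters(
            [tag("chr1", 100, 130, tag_id="a"), tag("chr1", 125, 150, tag_id="b")],
            min_depth=1,
        )
        assert len(clusters) == 1
        assert (clusters[0].interval.start, clusters[0].interval.end) == (100, 150)
        assert clusters[0].clip_count == 2

    def test_abutting_tags_do_not_merge(self):
        clusters = build_clusters(
            [tag("chr1", 100, 130), tag("chr1", 130, 160, tag_id="u")], min_depth=1
        )
        assert len(clusters) == 2

    def test_opposite_strands_do_not_merge(self):
        clusters = build_clusters(
            [tag("chr1", 100, 130, "+"), tag("chr1", 110, 140, "-")], min_depth=1
        )
        assert len(clusters) == 2

    def test_peak_depth_hand_built(self):
        # five tags all covering base 120, one distal tag
        tags = [tag("chr1", 100 + i, 121 + i, tag_id=f"t{i}") for i in range(5)]
        tags.append(tag("chr1", 5000, 5030, tag_id="far"))
        clusters = build_clusters(tags, min_depth=1)
        assert clusters[0].peak_depth == 5
        assert clusters[1].peak_depth == 1

    def test_min_depth_filters_singletons(self):
        tags = [tag("chr1", 0, 30), tag("chr1", 1000, 1030), tag("chr1", 1010, 1040, tag_id="u")]
        clusters = build_clusters(tags, min_depth=2)
        assert len(clusters) == 1 and clusters[0].interval.start == 1000

    def test_control_counts_by_interval_overlap(self):
        clip = [tag("chr1", 100, 130), tag("chr1", 120, 150, tag_id="u")]
        control = [
            tag("chr1", 90, 105, library="control"),
            tag("chr1", 149, 160, library="control", tag_id="c2"),
            tag("chr1", 150, 160, library="control", tag_id="c3"),  # abuts: no
            tag("chr1", 110, 140, "-", library="control", tag_id="c4"),  # strand
        ]
        (cluster,) = build_clusters(clip, min_depth=2, control_tags=control)
        assert cluster.control_count == 2


class TestScoreCluster:
    def test_equal_counts_equal_libraries(self):
        stats = LibraryStats(1000, 1000)
        fold, p = score_cluster(10, 10, stats)
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(float(exact_binom_tail(10, 20, Fraction(1, 2))))

    def test_all_mass_at_c(self):
        stats = LibraryStats(5000, 5000)
        fold, p = score_cluster(8, 0, stats)
        assert fold == pytest.approx(17.0)
        assert p == pytest.approx(0.00390625)  # (1/2)^8

    def test_degenerate_null_limit(self):
        # control library negligible -> pi ~ 1 -> p ~ 1 for any c
        stats = LibraryStats(10**9, 1)
        _, p = score_cluster(50, 0, stats)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_zero_clip_count_refused(self):
        with pytest.raises(ValueError):
            score_cluster(0, 5, LibraryStats(10, 10))

    def test_monotone_in_clip_count(self):
        stats = LibraryStats(2000, 1000)
        folds, ps = zip(*(score_cluster(c, 5, stats) for c in range(1, 30)))
        assert all(a < b for a, b in zip(folds, folds[1:]))
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_applied_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_empty_input(self):
        assert len(bh_fdr([])) == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=12),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariant(self, ps, rnd):
        perm = list(ps)
        rnd.shuffle(perm)
        order_a = np.argsort(ps, kind="stable")
        q_a = bh_fdr(ps)
        # same multiset of q-values regardless of input order
        assert sorted(q_a) == pytest.approx(sorted(bh_fdr(perm)))
        del order_a


class TestCallClusters:
    def test_empty_library_is_an_error(self):
        with pytest.raises(DataError):
            call_clusters([], [tag("chr1", 0, 10, library="control")])
        with pytest.raises(DataError):
            call_clusters([tag("chr1", 0, 10)], [])

    def test_control_copy_of_clip_yields_no_significance(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 5000, size=400)
        clip = [
            tag("chr1", int(s), int(s) + 30, tag_id=f"t{i}")
            for i, s in enumerate(starts)
        ]
        control = [
            tag("chr1", int(s), int(s) + 30, library="control", tag_id=f"c{i}")
            for i, s in enumerate(starts)
        ]
        clusters = call_clusters(clip, control)
        assert clusters and not any(c.significant for c in clusters)

    def test_output_sorted_by_position(self):
        clip = [
            tag("chr2", 500, 530, tag_id="a"), tag("chr2", 510, 540, tag_id="b"),
            tag("chr1", 100, 130, tag_id="c"), tag("chr1", 105, 135, tag_id="d"),
        ]
        control = [tag("chr1", 0, 20, library="control")]
        clusters = call_clusters(clip, control)
        keys = [(c.interval.chrom, c.interval.start) for c in clusters]
        assert keys == sorted(keys)
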