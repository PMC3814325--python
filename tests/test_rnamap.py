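"""Normalized complexity maps: indicators, normalization, control, peaks."""

import numpy as np
import pytest

from clip_splicemap.errors import DataError
from clip_splicemap.models import GeneModel, TranscriptModel
from clip_splicemap.rnamap import (
    ComplexityProfile,
    call_map_peaks,
    control_profile,
    event_coverage_indicator,
    exceedance_profile,
    normalized_complexity,
)

from conftest import iv, tag


class TestIndicator:
    def test_no_tags_all_zero(self, toy_cassette_event):
        ind = event_coverage_indicator([], toy_cassette_event, "cassette_5ss")
        assert ind.sum() == 0

    def test_plus_strand_coverage_arithmetic(self, toy_cassette_event):
        # 30-nt tag starting exactly at anchor+100 (anchor boundary = 1100)
        ind = event_coverage_indicator(
            [tag("chr1", 1200, 1230)], toy_cassette_event, "cassette_5ss"
        )
        covered = np.flatnonzero(ind) - 500
        assert covered.tolist() == list(range(100, 130))

    def test_minus_strand_same_transcript_offsets(self, toy_minus_event):
        # cassette_5ss boundary on '-' is event start (1000); offsets run to
        # decreasing genomic coordinates: d=100..129 -> bases 899..870.
        ind = event_coverage_indicator(
            [tag("chr2", 870, 900, "-")], toy_minus_event, "cassette_5ss"
        )
        covered = np.flatnonzero(ind) - 500
        assert covered.tolist() == list(range(100, 130))

    def test_opposite_strand_tag_ignored(self, toy_cassette_event):
        ind = event_coverage_indicator(
            [tag("chr1", 1200, 1230, "-")], toy_cassette_event, "cassette_5ss"
        )
        assert ind.sum() == 0


class TestNormalizedComplexity:
    def test_single_event_single_tag(self, toy_cassette_event):
        prof = normalized_complexity(
            [tag("chr1", 1100, 1101)], [toy_cassette_event], "cassette_5ss"
        )
        assert prof.values[500] == 1.0  # offset 0 = first intronic base
        assert prof.n_events == 1

    def test_fraction_of_covered_events(self, toy_cassette_event, toy_minus_event):
        events = [toy_cassette_event, toy_minus_event]
        prof = normalized_complexity(
            [tag("chr1", 1100, 1110)], events, "cassette_5ss"
        )
        assert prof.values[500] == 0.5

    def test_duplicating_one_events_tags_changes_nothing(self, toy_cassette_event, toy_minus_event):
        """Per-event saturation: the normalization property."""
        events = [toy_cassette_event, toy_minus_event]
        tags = [tag("chr1", 1150, 1180), tag("chr2", 870, 900, "-", tag_id="m")]
        base = normalized_complexity(tags, events, "cassette_5ss")
        dup = normalized_complexity(
            tags + [tag("chr1", 1150, 1180, tag_id=f"d{i}") for i in range(5)],
            events,
            "cassette_5ss",
        )
        assert np.array_equal(base.values, dup.values)

    def test_values_in_unit_interval_and_integer_counts(self, toy_cassette_event):
        rng = np.random.default_rng(0)
        tags = [
            tag("chr1", int(s), int(s) + 20, tag_id=f"t{i}")
            for i, s in enumerate(rng.integers(600, 1600, size=200))
        ]
        prof = normalized_complexity(tags, [toy_cassette_event], "cassette_3ss")
        assert prof.values.min() >= 0 and prof.values.max() <= 1
        counts = prof.values * prof.n_events
        assert np.allclose(counts, np.round(counts))

    def test_empty_event_list_refused(self):
        with pytest.raises(DataError):
            normalized_complexity([], [], "cassette_5ss")


def expressed_genes(n=40, seed=0):
    rng = np.random.default_rng(seed)
    genes = []
    pos = 1000
    for i in range(n):
        exons = []
        for j in range(5):
            ln = int(rng.integers(100, 150))
            exons.append(iv("chrC", pos, pos + ln))
            pos += ln + int(rng.integers(800, 1200))
        pos += 2000
        genes.append(
            GeneModel(
                f"g{i}",
                (
                    TranscriptModel(
                        f"t{i}", f"g{i}", exons=tuple(exons),
                        exon_roles=tuple(["constitutive"] * 5),
                    ),
                ),
            )
        )
    return genes


class TestControlProfile:
    def test_requires_enough_constitutive_exons(self):
        genes = expressed_genes(2)
        with pytest.raises(DataError, match="constitutive"):
            control_profile([], genes, set_size=50, n_sets=2)

    def test_deterministic_under_seed(self):
        genes = expressed_genes()
        tags = [tag("chrC", 1000 + 37 * i, 1025 + 37 * i, tag_id=f"t{i}") for i in range(300)]
        a = control_profile(tags, genes, set_size=10, n_sets=5, seed=3)
        b = control_profile(tags, genes, set_size=10, n_sets=5, seed=3)
        for kind in ("3ss", "5ss"):
            assert np.array_equal(a.sets[kind], b.sets[kind])

    def test_two_sets_minimal_sd_defined(self):
        genes = expressed_genes()
        ctrl = control_profile([], genes, set_size=5, n_sets=2, seed=1)
        assert np.all(ctrl.sd("cassette_5ss") >= 0)

    def test_background_tags_give_flat_control_mean(self):
        """Uniform background: control mean max-minus-min < 5 pooled sd."""
        genes = expressed_genes(60, seed=2)
        rng = np.random.default_rng(4)
        total = genes[-1].span.end
        tags = [
            tag("chrC", int(s), int(s) + 20, tag_id=f"t{i}")
            for i, s in enumerate(rng.integers(1000, total, size=4000))
        ]
        ctrl = control_profile(tags, genes, set_size=30, n_sets=50, seed=5)
        mean = ctrl.mean("cassette_5ss")
        pooled_sd = ctrl.sd("cassette_5ss").mean()
        assert mean.max() - mean.min() < 5 * pooled_sd


class TestCallMapPeaks:
    def make_control(self, window=500, n_sets=50, set_size=30, level=0.2, seed=0):
        rng = np.random.default_rng(seed)
        sets = rng.binomial(set_size, level, size=(n_sets, 2 * window + 1)) / set_size
        from clip_splicemap.rnamap import ControlProfile

        return ControlProfile(
            offsets=np.arange(-window, window + 1),
            sets={"3ss": sets, "5ss": sets.copy()},
            n_sets=n_sets,
            set_size=set_size,
        )

    def profile_with_bumps(self, bumps, window=500, level=0.2, n_events=200, seed=1):
        rng = np.random.default_rng(seed)
        offs = np.arange(-window, window + 1)
        p = np.full(offs.size, level)
        for center, height in bumps:
            p = np.maximum(p, level + height * np.exp(-((offs - center) ** 2) / 800.0))
        vals = rng.binomial(n_events, p, size=offs.size) / n_events
        return ComplexityProfile("cassette_5ss", offs, vals, n_events)

    def test_profile_equal_to_control_has_no_peaks(self):
        control = self.make_control()
        profile = ComplexityProfile(
            "cassette_5ss",
            control.offsets,
            control.sets["5ss"].mean(axis=0),
            30,
        )
        assert call_map_peaks(profile, control) == []

    def test_two_planted_bumps_two_peaks_ordered(self):
        control = self.make_control()
        profile = self.profile_with_bumps([(100, 0.7), (400, 0.7)])
        peaks = call_map_peaks(profile, control)
        assert len(peaks) == 2
        assert abs(peaks[0].offset - 100) <= 20
        assert abs(peaks[1].offset - 400) <= 20
        assert all(p.exceedance >= 3.0 for p in peaks)

    def test_smoothing_validation(self):
        control = self.make_control()
        profile = self.profile_with_bumps([(100, 0.5)])
        with pytest.raises(ValueError):
            call_map_peaks(profile, control, smoothing=10)
        with pytest.raises(ValueError):
            call_map_peaks(profile, control, smoothing=501 + 2)

    def test_exceedance_profile_shapes(self):
        control = self.make_control()
        profile = self.profile_with_bumps([(0, 0.5)])
        sm_v, sm_m, sm_sd, ex = exceedance_profile(profile, control)
        assert sm_v.shape == sm_m.shape == sm_sd.shape == ex.shape
        assert ex[abs(control.offsets) < 10].max() > 3
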