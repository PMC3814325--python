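"""Splicing-quantification formulas and the AS-NMD predictor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clip_splicemap.models import GenomicInterval, TranscriptModel
from clip_splicemap.quantify import (
    BandPair,
    ddct_relative_expression,
    predict_nmd,
    reduction_relative_to_mock,
    skip_exon,
    skipping_ratio,
)
from clip_splicemap.simulate import fus_like_fixture, simulate_band_intensities

from conftest import iv


def oracle_first_stop(seq: str, cds_start: int):
    """Independent codon-scan oracle built on Biopython translation."""
    from Bio.Seq import Seq

    coding = seq[cds_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    idx = protein.find("*")
    return None if idx == -1 else cds_start + 3 * idx


class TestFormulas:
    @pytest.mark.parametrize(
        "skipped,included,expected",
        [(50, 50, 0.5), (0, 80, 0.0), (30, 70, 0.3)],
    )
    def test_skipping_ratio(self, skipped, included, expected):
        assert skipping_ratio(BandPair(skipped, included)).skipping_ratio == expected

    def test_skipping_ratio_both_zero_errors(self):
        with pytest.raises(ValueError):
            BandPair(0, 0)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_skipping_ratio_scale_invariant(self, s, i, c):
        a = skipping_ratio(BandPair(s, i)).skipping_ratio
        b = skipping_ratio(BandPair(c * s, c * i)).skipping_ratio
        assert a == pytest.approx(b, rel=1e-9)

    @pytest.mark.parametrize(
        "treated,mock,expected", [(15, 100, 0.15), (70, 70, 1.0), (0, 50, 0.0)]
    )
    def test_reduction_relative_to_mock(self, treated, mock, expected):
        assert reduction_relative_to_mock(treated, mock).fraction_of_mock == expected

    def test_reduction_requires_positive_mock(self):
        with pytest.raises(ValueError):
            reduction_relative_to_mock(10, 0)

    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20, 15, 20, 15), 1.0),
            ((21, 15, 20, 15), 0.5),  # ddCt = 1
            ((18, 15, 20, 15), 4.0),  # ddCt = -2
        ],
    )
    def test_ddct(self, cts, expected):
        assert ddct_relative_expression(*cts) == pytest.approx(expected)


class TestBandSimulation:
    def test_noiseless_is_exact(self):
        pairs = simulate_band_intensities(0.3, 100.0, cv=0.0, n=20, seed=1)
        assert all(
            skipping_ratio(p).skipping_ratio == pytest.approx(0.3) for p in pairs
        )

    def test_zero_ratio_zero_band(self):
        pairs = simulate_band_intensities(0.0, 100.0, cv=0.2, n=20, seed=1)
        assert all(p.skipped_intensity == 0 for p in pairs)

    @pytest.mark.parametrize("truth", [0.1, 0.5, 0.9])
    def test_monte_carlo_recovery(self, truth):
        pairs = simulate_band_intensities(truth, 100.0, cv=0.1, n=1000, seed=7)
        mean = np.mean([skipping_ratio(p).skipping_ratio for p in pairs])
        assert abs(mean - truth) < 0.02


def make_transcript(exon_lengths, cds_start, cds_end, gap=200):
    exons, pos = [], 1000
    for ln in exon_lengths:
        exons.append(iv("chrT", pos, pos + ln))
        pos += ln + gap
    return TranscriptModel(
        "tt", "gt", exons=tuple(exons), cds_start=cds_start, cds_end=cds_end
    )


class TestSkipExon:
    def test_sequence_is_concatenation_without_exon(self):
        t = make_transcript([100, 90, 200], 10, 370)
        seq = "A" * 100 + "C" * 90 + "G" * 200
        skipped, new_seq = skip_exon(t, 1, seq)
        assert new_seq == "A" * 100 + "G" * 200
        assert skipped.skipped_exon_length == 90

    def test_last_junction_shifts(self):
        t = make_transcript([100, 90, 200], 10, 370)
        assert t.last_junction == 190
        skipped, _ = skip_exon(t, 1)
        assert skipped.last_junction == 100

    def test_terminal_exon_refused(self):
        t = make_transcript([100, 90, 200], 10, 370)
        for idx in (0, 2):
            with pytest.raises(ValueError):
                skip_exon(t, idx)

    def test_start_codon_in_removed_exon_refused(self):
        t = make_transcript([100, 90, 200], 120, 370)
        with pytest.raises(ValueError, match="start codon"):
            skip_exon(t, 1)


class TestPredictNmd:
    def test_frame_preserving_skip_no_new_stop(self):
        rng = np.random.default_rng(3)
        non_stop = [c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3)) if c not in ("TAA", "TAG", "TGA")]
        lengths = [60, 90, 120]  # middle exon divisible by 3
        total = sum(lengths)
        codons = [non_stop[i] for i in rng.integers(0, len(non_stop), total // 3 - 1)]
        seq = "ATG" + "".join(codons)
        seq = seq[: total - 3] + "TAA"
        t = make_transcript(lengths, 0, total)
        skipped, sseq = skip_exon(t, 1, seq)
        call = predict_nmd(skipped, sseq)
        assert call.frameshift is False
        assert call.nmd is False

    def test_agrees_with_translation_oracle_on_fuzzed_transcripts(self):
        """200 random toy transcripts: first-stop position, PTC flag and the
        50-nt junction rule all match a Biopython-based oracle."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_exons = int(rng.integers(3, 9))
            lengths = [int(rng.integers(30, 200)) for _ in range(n_exons)]
            total = sum(lengths)
            cds_start = int(rng.integers(0, 30))
            cds_len = 3 * int(rng.integers(10, (total - cds_start) // 3 + 1))
            cds_end = cds_start + cds_len
            seq = "".join(
                np.array(list("ACGT"))[rng.integers(0, 4, size=total)]
            )
            t = make_transcript(lengths, cds_start, cds_end)
            call = predict_nmd(t, seq)
            stop = oracle_first_stop(seq, cds_start)
            if stop is None:
                assert call.no_stop and not call.nmd
                continue
            ptc = stop if stop < cds_end - 3 else None
            assert call.ptc_position == ptc
            last_junction = total - lengths[-1]
            expected_nmd = ptc is not None and (last_junction - ptc) > 50
            assert call.nmd == expected_nmd

    def test_frameshift_bookkeeping_matches_removed_length(self):
        """skip_exon then predict_nmd reports a frameshift exactly when the
        removed exon length is not divisible by 3."""
        rng = np.random.default_rng(23)
        for _ in range(50):
            n_exons = int(rng.integers(3, 7))
            lengths = [int(rng.integers(30, 120)) for _ in range(n_exons)]
            idx = int(rng.integers(1, n_exons - 1))
            total = sum(lengths)
            t = make_transcript(lengths, 3, 3 + 3 * ((total - 6) // 3))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=total)])
            try:
                skipped, sseq = skip_exon(t, idx, seq)
            except ValueError:
                continue  # degenerate CDS after removal
            call = predict_nmd(skipped, sseq)
            assert call.frameshift == (lengths[idx] % 3 != 0)

    def test_noncoding_transcript_refused(self):
        t = TranscriptModel("t", "g", exons=(iv("chrT", 0, 90),))
        with pytest.raises(ValueError, match="non-coding"):
            predict_nmd(t, "A" * 90)


class TestFixture:
    def test_cassette_exon_length_breaks_frame(self):
        model, seq = fus_like_fixture()
        assert len(model.exons) == 15
        assert len(model.exons_transcript_order()[6]) % 3 != 0
        assert len(seq) == model.length

    def test_full_isoform_is_clean(self):
        model, seq = fus_like_fixture()
        call = predict_nmd(model, seq)
        assert call.ptc_position is None and not call.nmd

    def test_skipped_isoform_is_an_nmd_substrate_with_ptc_in_exon8(self):
        model, seq = fus_like_fixture()
        skipped, sseq = skip_exon(model, 6, seq)
        call = predict_nmd(skipped, sseq)
        assert call.frameshift is True
        assert call.nmd is True
        # exon-8 segment of the skipped transcript (exon 7 removed)
        lengths = skipped.exon_lengths_transcript_order()
        e8_start = sum(lengths[:6])
        e8_end = e8_start + lengths[6]
        assert e8_start <= call.ptc_position < e8_end
        assert call.ptc_to_last_junction > 50
        # cross-check against the independent translation oracle
        assert call.ptc_position == oracle_first_stop(sseq, skipped.cds_start)
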