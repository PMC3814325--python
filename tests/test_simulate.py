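"""Synthetic-data generator: determinism, mixture structure, planted signal."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from clip_splicemap.anchors import anchor_boundary, offset_to_base
from clip_splicemap.simulate import (
    BindingPeakSpec,
    SimulationConfig,
    generate_annotation,
    simulate_clip_library,
    simulate_control_library,
    simulate_enriched_dataset,
    write_dataset,
)


def small_config(seed=1, **kw):
    defaults = dict(
        n_genes=20,
        cassette_fraction=0.5,
        retained_intron_fraction=0.0,
        clip_library_size=5000,
        control_library_size=5000,
    )
    defaults.update(kw)
    return SimulationConfig(seed=seed, **defaults)


class TestAnnotation:
    def test_cassette_events_have_constitutive_flanks(self):
        ds = generate_annotation(small_config())
        cassette = [e for e in ds.events if e.category == "cassette_exon"]
        assert len(cassette) == 10
        assert all(e.flanking_constitutive for e in cassette)
        for ev in cassette:
            # flanking introns abut event and exons by construction
            assert ev.upstream_intron is not None

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for run in ("a", "b"):
            cfg = small_config()
            ds = generate_annotation(cfg)
            clip = simulate_clip_library(ds)
            control = simulate_control_library(ds)
            write_dataset(ds, clip, control, tmp_path / run)
        for name in ("genome.fa", "annotation.gtf", "clip_tags.bed",
                     "control_tags.bed", "alt_events.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_annotation(small_config(seed=1)).genome
        b = generate_annotation(small_config(seed=2)).genome
        assert a != b

    def test_unplanted_motif_occurs_at_background_rate(self):
        cfg = small_config(motif_prob=0.0, n_genes=40)
        ds = generate_annotation(cfg)
        motif_dna = "CAGGTT"
        count = sum(g.count(motif_dna) for g in ds.genome.values())
        positions = sum(len(g) - 5 for g in ds.genome.values())
        # binomial expectation at 4^-6 per position, +/- 5 sd
        expected = positions * 4.0**-6
        sd = np.sqrt(expected)
        assert abs(count - expected) < 5 * sd

    def test_planted_motif_enriched_in_peak_regions(self):
        cfg = small_config(motif_prob=1.0, n_genes=40)
        ds = generate_annotation(cfg)
        cassette = [e for e in ds.events if e.category == "cassette_exon"]
        hits = 0
        for ev in cassette:
            for peak in cfg.peaks:
                b = anchor_boundary(ev, peak.anchor)
                p0 = offset_to_base(b, ev.strand, peak.offset)
                lo = min(p0 - 6, p0 + 6)
                seq = ds.genome[ev.chrom][lo : lo + 13]
                if ev.strand == "+":
                    hits += "CAGGTT" in seq
                else:
                    hits += "AACCTG" in seq
        assert hits == len(cassette) * len(cfg.peaks)

    def test_peak_collision_validation(self):
        with pytest.raises(ValueError, match="collide"):
            small_config(
                intron_length=(300, 400),
                peaks=(BindingPeakSpec("cassette_5ss", 400, 30.0, 0.5),),
            )

    def test_weights_must_sum_with_background(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(background_fraction=0.9)


class TestLibraries:
    def test_exact_library_sizes(self):
        ds = generate_annotation(small_config())
        assert len(simulate_clip_library(ds, size=1234)) == 1234
        assert len(simulate_control_library(ds, size=987)) == 987

    def test_background_only_is_uniform_over_transcribed_bases(self):
        """Chi-square GOF of tag 5'-end counts across gene spans."""
        ds = generate_annotation(small_config())
        tags = simulate_clip_library(ds, background_fraction=1.0, size=50_000)
        spans = {g.gene_id: g.span for g in ds.genes}
        counts = {gid: 0 for gid in spans}
        for t in tags:
            iv = t.interval
            pos = iv.start if iv.strand == "+" else iv.end - 1
            for gid, span in spans.items():
                if span.chrom == iv.chrom and span.start <= pos < span.end:
                    counts[gid] += 1
                    break
        total_len = sum(len(s) for s in spans.values())
        expected = np.array(
            [50_000 * len(s) / total_len for s in spans.values()]
        )
        observed = np.array([counts[g] for g in spans])
        assert sps.chisquare(observed, expected).pvalue > 0.01

    def test_single_peak_mode_at_configured_offset(self):
        """Tag-start histogram mode within 100 +/- 10 of the cassette 5'ss."""
        peaks = (BindingPeakSpec("cassette_5ss", 100, 30.0, 0.8),)
        cfg = small_config(background_fraction=0.2, peaks=peaks)
        ds = generate_annotation(cfg)
        tags = simulate_clip_library(ds, size=30_000)
        cassette = [e for e in ds.events if e.category == "cassette_exon"]
        offsets = []
        for t in tags:
            iv = t.interval
            start = iv.start if iv.strand == "+" else iv.end - 1
            for ev in cassette:
                if ev.chrom != iv.chrom or ev.strand != iv.strand:
                    continue
                b = anchor_boundary(ev, "cassette_5ss")
                d = (start - b) if ev.strand == "+" else (b - 1 - start)
                if -500 <= d <= 500:
                    offsets.append(d)
        hist, edges = np.histogram(offsets, bins=np.arange(-500, 502) - 0.5)
        mode = int(edges[np.argmax(hist)] + 0.5)
        assert abs(mode - 100) <= 10

    def test_control_library_has_no_anchor_enrichment(self):
        """Mean control coverage within +/-200 of cassette 5'ss matches the
        genome-wide background rate (no positional peak)."""
        ds = generate_annotation(small_config())
        control = simulate_control_library(ds, size=30_000)
        from clip_splicemap.rnamap import normalized_complexity

        cassette = [e for e in ds.events if e.category == "cassette_exon"]
        prof = normalized_complexity(control, cassette, "cassette_5ss", window=500)
        near = prof.values[300:701].mean()  # offsets -200..200
        far = np.concatenate([prof.values[:200], prof.values[-200:]]).mean()
        assert abs(near - far) < 0.1

    def test_minus_strand_offsets_run_against_genomic_coordinates(self):
        """On a minus-strand gene, +100 downstream of the 5'ss means 100 nt
        toward smaller genomic coordinates."""
        peaks = (BindingPeakSpec("cassette_5ss", 100, 5.0, 0.9),)
        cfg = small_config(background_fraction=0.1, peaks=peaks, n_genes=4)
        ds = generate_annotation(cfg)
        minus = [
            e for e in ds.events
            if e.category == "cassette_exon" and e.strand == "-"
        ]
        assert minus
        tags = simulate_clip_library(ds, size=2000)
        ev = minus[0]
        b = anchor_boundary(ev, "cassette_5ss")  # = event_interval.start
        starts = [
            t.interval.end - 1
            for t in tags
            if t.interval.chrom == ev.chrom
            and t.interval.strand == "-"
            and abs((b - 1 - (t.interval.end - 1)) - 100) <= 20
        ]
        assert len(starts) > 10  # mass concentrates at genomic b-101


class TestEnrichedScenario:
    def test_sites_and_fold_geometry(self):
        sim = simulate_enriched_dataset(seed=1, n_genes=10, library_size=10_000)
        assert len(sim.sites) == 10
        cfg = sim.dataset.config
        assert 0.0 < cfg.background_fraction < 1.0
        # in-site CLIP density ~ fold x control density
        from clip_splicemap._index import StrandedIntervalArrays

        clip_idx = StrandedIntervalArrays(t.interval for t in sim.clip_tags)
        ctrl_idx = StrandedIntervalArrays(t.interval for t in sim.control_tags)
        in_clip = sum(clip_idx.count_overlapping(s) for s in sim.sites)
        in_ctrl = sum(ctrl_idx.count_overlapping(s) for s in sim.sites)
        assert in_clip / max(in_ctrl, 1) == pytest.approx(10.0, rel=0.25)
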