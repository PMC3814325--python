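"""Synthetic genome, annotation, and CLIP-library generator.

Every downstream stage of the pipeline is exercised against data produced
here: genes with cassette exons flanked by constitutive exons, CLIP tag
pileups at configured offsets from exon boundaries on top of a uniform
background, a background-only control library, planted sequence motifs,
and noisy two-band gel intensities with a known true skipping ratio.

All generators are pure functions of (config, seed): the same inputs give
byte-identical output. Tag *starts* (5' ends) follow the peak distribution,
mirroring 5'-end-driven CLIP chemistry; tag length is drawn independently.
Peaks are placed relative to cassette events only, so constitutive exons
receive background signal only and the cassette-vs-constitutive contrast is
reproducible by construction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .anchors import anchor_boundary, offset_to_base
from .models import (
    ANCHORS,
    AltEvent,
    ClipTag,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from .quantify import BandPair, predict_nmd, skip_exon

_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BindingPeakSpec:
    """One positional binding peak relative to a cassette-event anchor.

    ``offset`` is transcript-oriented (positive = toward the transcript 3'
    end); ``width`` is the standard deviation of tag 5'-end placement (nt);
    ``weight`` is the fraction of total library mass the peak carries.
    """

    anchor: str
    offset: int
    width: float
    weight: float

    def __post_init__(self) -> None:
        if self.anchor not in ANCHORS:
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.weight < 0:
            raise ValueError("peak weight must be >= 0")


#: Default binding geometry: the four-peak arrangement around cassette
#: exons (highest peak within ~100 nt downstream of the cassette 5' splice
#: site; a peak ~150 nt upstream of the cassette 3' splice site; a second
#: downstream peak near +400; and a peak ~300 nt downstream of the upstream
#: constitutive exon's 5' splice site).
DEFAULT_PEAKS: tuple[BindingPeakSpec, ...] = (
    BindingPeakSpec("cassette_5ss", 100, 30.0, 0.20),
    BindingPeakSpec("cassette_3ss", -150, 30.0, 0.10),
    BindingPeakSpec("cassette_5ss", 400, 30.0, 0.10),
    BindingPeakSpec("upstream_exon_5ss", 300, 30.0, 0.10),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults are the package's standard simulation: 120 expressed
    genes, a quarter carrying a cassette exon with constitutive flanks, the
    four-peak default binding geometry holding half the CLIP library mass
    over a uniform background, and libraries of 20k tags each.
    """

    seed: int
    n_genes: int = 120
    exons_per_gene: tuple[int, int] = (6, 8)
    exon_length: tuple[int, int] = (120, 180)
    intron_length: tuple[int, int] = (1200, 1800)
    cassette_fraction: float = 0.25
    retained_intron_fraction: float = 0.1
    motif: str = "CAGGUU"
    motif_prob: float = 0.6
    peaks: tuple[BindingPeakSpec, ...] = DEFAULT_PEAKS
    tag_length: tuple[int, int] = (20, 30)
    clip_library_size: int = 20_000
    control_library_size: int = 20_000
    background_fraction: float = 0.5
    genes_per_chrom: int = 10
    intergenic_gap: int = 2000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_genes", "clip_library_size", "control_library_size",
                     "genes_per_chrom", "intergenic_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "tag_length"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.exons_per_gene[0] < 4:
            raise ValueError("need at least 4 exons per gene for internal "
                             "cassette exons with internal flanks")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        total = self.background_fraction + sum(p.weight for p in self.peaks)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"peak weights plus background fraction must sum to 1 "
                f"(got {total:.6f})"
            )
        if set(self.motif.upper()) - set("ACGU"):
            raise ValueError("motif must be an RNA string over ACGU")
        min_intron = self.intron_length[0]
        for p in self.peaks:
            need = 2 * (abs(p.offset) + p.width)
            if min_intron < need:
                raise ValueError(
                    f"intron length {min_intron} too short for peak at "
                    f"{p.anchor}{p.offset:+d} (width {p.width}): peaks would "
                    f"collide with exon boundaries (need >= {need:.0f})"
                )


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated genome with its annotation and splicing events."""

    genome: dict[str, str]
    genes: tuple[GeneModel, ...]
    events: tuple[AltEvent, ...]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Annotation + genome
# ---------------------------------------------------------------------------


def generate_annotation(
    config: SimulationConfig, seed: Optional[int] = None
) -> SyntheticDataset:
    """Generate the toy genome, gene models, and splicing-event table.

    Every cassette exon is internal with internal constitutive flanking
    exons (``flanking_constitutive`` is true for those events). The genome
    is uniform over ACGT except for motif instances planted (as DNA, in
    transcript orientation) at the configured peak offsets of cassette
    events with probability ``motif_prob`` per (event, peak).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes
    n_cassette = int(round(n * config.cassette_fraction))
    n_ri = int(round(n * config.retained_intron_fraction))
    if n_cassette + n_ri > n:
        raise ValueError("cassette and retained-intron fractions exceed 1")
    special = rng.choice(n, size=n_cassette + n_ri, replace=False)
    cassette_genes = set(int(i) for i in special[:n_cassette])
    ri_genes = set(int(i) for i in special[n_cassette:])

    genes: list[GeneModel] = []
    events: list[AltEvent] = []
    chrom_cursor: dict[str, int] = {}
    chrom_order: list[str] = []

    for gi in range(n):
        chrom = f"chr{gi // config.genes_per_chrom + 1}"
        if chrom not in chrom_cursor:
            chrom_cursor[chrom] = config.intergenic_gap
            chrom_order.append(chrom)
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0],
                                 config.exon_length[1] + 1, size=n_exons)
        intron_lens = rng.integers(config.intron_length[0],
                                   config.intron_length[1] + 1,
                                   size=n_exons - 1)
        start = chrom_cursor[chrom]
        exons: list[GenomicInterval] = []
        pos = start
        for j in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[j]), strand))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        chrom_cursor[chrom] = pos + config.intergenic_gap

        gene_id = f"g{gi + 1:03d}"
        roles = ["constitutive"] * n_exons
        cassette_t_idx: Optional[int] = None
        ri_t_idx: Optional[int] = None
        if gi in cassette_genes:
            cassette_t_idx = int(rng.integers(1, n_exons - 1))
        elif gi in ri_genes:
            ri_t_idx = int(rng.integers(1, n_exons - 2))

        def t2g(t_idx: int) -> int:
            # transcript-order exon index -> genomic-order index
            return t_idx if strand == "+" else n_exons - 1 - t_idx

        if cassette_t_idx is not None:
            roles[t2g(cassette_t_idx)] = "cassette"

        length = int(exon_lens.sum())
        cds_start = 30
        cds_end = cds_start + 3 * ((length - cds_start - 15) // 3)
        transcript = TranscriptModel(
            transcript_id=f"t{gi + 1:03d}",
            gene_id=gene_id,
            exons=tuple(exons),
            cds_start=cds_start,
            cds_end=cds_end,
            exon_roles=tuple(roles),
        )
        genes.append(GeneModel(gene_id, (transcript,), expressed=True))

        exons_t = transcript.exons_transcript_order()
        if cassette_t_idx is not None:
            i = cassette_t_idx
            up_e, cas, down_e = exons_t[i - 1], exons_t[i], exons_t[i + 1]
            if strand == "+":
                up_i = GenomicInterval(chrom, up_e.end, cas.start, strand)
                down_i = GenomicInterval(chrom, cas.end, down_e.start, strand)
            else:
                up_i = GenomicInterval(chrom, cas.end, up_e.start, strand)
                down_i = GenomicInterval(chrom, down_e.end, cas.start, strand)
            events.append(
                AltEvent(
                    event_id=f"ev_cas_{gene_id}",
                    category="cassette_exon",
                    event_interval=cas,
                    upstream_exon=up_e,
                    downstream_exon=down_e,
                    upstream_intron=up_i,
                    downstream_intron=down_i,
                    host_gene=gene_id,
                    flanking_constitutive=True,
                )
            )
        if ri_t_idx is not None:
            i = ri_t_idx
            up_e, down_e = exons_t[i], exons_t[i + 1]
            if strand == "+":
                intron = GenomicInterval(chrom, up_e.end, down_e.start, strand)
            else:
                intron = GenomicInterval(chrom, down_e.end, up_e.start, strand)
            events.append(
                AltEvent(
                    event_id=f"ev_ri_{gene_id}",
                    category="retained_intron",
                    event_interval=intron,
                    upstream_exon=up_e,
                    downstream_exon=down_e,
                    host_gene=gene_id,
                    flanking_constitutive=True,
                )
            )

    # Genome: uniform ACGT, then motif planting inside designated peak regions.
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome_arrays: dict[str, np.ndarray] = {}
    for chrom in chrom_order:
        size = chrom_cursor[chrom]
        genome_arrays[chrom] = alphabet[rng.integers(0, 4, size=size)].copy()

    motif_dna = config.motif.upper().translate(_RNA_TO_DNA)
    k = len(motif_dna)
    plus_bytes = np.frombuffer(motif_dna.encode(), dtype=np.uint8)
    minus_bytes = np.frombuffer(_revcomp(motif_dna).encode(), dtype=np.uint8)
    for ev in events:
        if ev.category != "cassette_exon":
            continue
        for peak in config.peaks:
            if rng.random() >= config.motif_prob:
                continue
            boundary = anchor_boundary(ev, peak.anchor)
            pos0 = offset_to_base(boundary, ev.strand, peak.offset)
            arr = genome_arrays[ev.chrom]
            if ev.strand == "+":
                lo, hi, word = pos0, pos0 + k, plus_bytes
            else:
                lo, hi, word = pos0 - k + 1, pos0 + 1, minus_bytes
            if 0 <= lo and hi <= len(arr):
                arr[lo:hi] = word

    genome = {c: a.tobytes().decode() for c, a in genome_arrays.items()}
    return SyntheticDataset(
        genome=genome, genes=tuple(genes), events=tuple(events), config=config
    )


# ---------------------------------------------------------------------------
# Tag libraries
# ---------------------------------------------------------------------------


def _span_arrays(genes: Sequence[GeneModel]):
    spans = [g.span for g in genes]
    lengths = np.array([len(s) for s in spans], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    return spans, lengths, cum


def _host_feature(gene: GeneModel, base: int) -> GenomicInterval:
    """The exon or intron of the gene containing a genomic base."""
    t = gene.transcripts[0]
    for exon in t.exons:
        if exon.start <= base < exon.end:
            return exon
    for a, b in zip(t.exons, t.exons[1:]):
        if a.end <= base < b.start:
            return GenomicInterval(gene.chrom, a.end, b.start, gene.strand)
    raise ValueError(
        f"base {base} outside transcribed span of {gene.gene_id}"
    )


def _emit_tags(
    chroms: list[str],
    strands: list[str],
    five_prime: np.ndarray,
    lengths: np.ndarray,
    library: str,
) -> list[ClipTag]:
    tags = []
    for i, (chrom, strand) in enumerate(zip(chroms, strands)):
        p, ln = int(five_prime[i]), int(lengths[i])
        if strand == "+":
            start, end = p, p + ln
        else:
            start, end = p - ln + 1, p + 1
        start = max(start, 0)
        tags.append(
            ClipTag(
                GenomicInterval(chrom, start, end, strand),
                library=library,
                tag_id=f"{library}_{i:06d}",
            )
        )
    return tags


def simulate_clip_library(
    dataset: SyntheticDataset,
    seed: Optional[int] = None,
    peaks: Optional[Sequence[BindingPeakSpec]] = None,
    background_fraction: Optional[float] = None,
    size: Optional[int] = None,
) -> list[ClipTag]:
    """Simulate the CLIP library: uniform background plus positional peaks.

    Each tag is background with probability ``background_fraction`` (5' end
    uniform over transcribed gene spans); otherwise a peak is picked by
    weight, a cassette event uniformly, and the tag 5' end drawn as
    ``round(Normal(anchor + oriented offset, width))``, clipped to the
    intron/exon hosting the peak. Tag strand is the gene strand; the library
    size is exact.
    """
    config = dataset.config
    peaks = tuple(peaks if peaks is not None else config.peaks)
    bg = (
        config.background_fraction
        if background_fraction is None
        else background_fraction
    )
    n = size if size is not None else config.clip_library_size
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    cassette_events = [e for e in dataset.events if e.category == "cassette_exon"]
    if bg < 1.0:
        if not peaks:
            raise ValueError("background_fraction < 1 requires peak specs")
        if not cassette_events:
            raise ValueError("no cassette events to anchor peaks on")

    genes_by_id = {g.gene_id: g for g in dataset.genes}
    spans, span_lengths, cum = _span_arrays(dataset.genes)
    total = int(cum[-1])

    lengths = rng.integers(config.tag_length[0], config.tag_length[1] + 1, size=n)
    is_bg = rng.random(n) < bg

    chroms: list[str] = [""] * n
    strands: list[str] = [""] * n
    five = np.zeros(n, dtype=np.int64)

    # Background: uniform over the union of transcribed spans.
    bg_idx = np.flatnonzero(is_bg)
    if bg_idx.size:
        u = rng.integers(0, total, size=bg_idx.size)
        gidx = np.searchsorted(cum, u, side="right") - 1
        for i, g in zip(bg_idx, gidx):
            chroms[i] = spans[g].chrom
            strands[i] = spans[g].strand
        five[bg_idx] = np.array([spans[g].start for g in gidx]) + (u - cum[gidx])

    # Signal: peak by weight, cassette event uniform, normal jitter.
    sig_idx = np.flatnonzero(~is_bg)
    if sig_idx.size:
        weights = np.array([p.weight for p in peaks], dtype=float)
        weights = weights / weights.sum()
        peak_choice = rng.choice(len(peaks), size=sig_idx.size, p=weights)
        event_choice = rng.integers(0, len(cassette_events), size=sig_idx.size)
        jitter = rng.normal(0.0, 1.0, size=sig_idx.size)

        # Pre-resolve anchors and host features per (event, peak).
        anchor_base = np.zeros((len(cassette_events), len(peaks)), dtype=np.int64)
        host_lo = np.zeros_like(anchor_base)
        host_hi = np.zeros_like(anchor_base)
        directions = np.zeros(len(cassette_events), dtype=np.int64)
        for ei, ev in enumerate(cassette_events):
            directions[ei] = 1 if ev.strand == "+" else -1
            gene = genes_by_id[ev.host_gene]
            for pi, peak in enumerate(peaks):
                boundary = anchor_boundary(ev, peak.anchor)
                base = offset_to_base(boundary, ev.strand, peak.offset)
                host = _host_feature(gene, base)
                anchor_base[ei, pi] = base
                host_lo[ei, pi] = host.start
                host_hi[ei, pi] = host.end - 1

        widths = np.array([p.width for p in peaks])
        offs = np.rint(jitter * widths[peak_choice]).astype(np.int64)
        base = anchor_base[event_choice, peak_choice]
        pos = base + directions[event_choice] * offs
        pos = np.clip(
            pos, host_lo[event_choice, peak_choice], host_hi[event_choice, peak_choice]
        )
        five[sig_idx] = pos
        for i, ei in zip(sig_idx, event_choice):
            ev = cassette_events[ei]
            chroms[i] = ev.chrom
            strands[i] = ev.strand

    return _emit_tags(chroms, strands, five, lengths, "clip")


def simulate_control_library(
    dataset: SyntheticDataset,
    seed: Optional[int] = None,
    size: Optional[int] = None,
) -> list[ClipTag]:
    """Simulate the control (nonspecific-antibody) library: background only."""
    config = dataset.config
    n = size if size is not None else config.control_library_size
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    spans, span_lengths, cum = _span_arrays(dataset.genes)
    total = int(cum[-1])
    lengths = rng.integers(config.tag_length[0], config.tag_length[1] + 1, size=n)
    u = rng.integers(0, total, size=n)
    gidx = np.searchsorted(cum, u, side="right") - 1
    five = np.array([spans[g].start for g in gidx]) + (u - cum[gidx])
    chroms = [spans[g].chrom for g in gidx]
    strands = [spans[g].strand for g in gidx]
    return _emit_tags(chroms, strands, five, lengths, "control")


# ---------------------------------------------------------------------------
# Enriched-site scenario (known-truth benchmark for cluster calling)
# ---------------------------------------------------------------------------


def planted_site_intervals(
    events: Sequence[AltEvent], peaks: Sequence[BindingPeakSpec]
) -> list[GenomicInterval]:
    """Truth intervals of planted sites: anchor offset +/- 2 peak widths."""
    sites = []
    for ev in events:
        if ev.category != "cassette_exon":
            continue
        for peak in peaks:
            boundary = anchor_boundary(ev, peak.anchor)
            half = int(round(2 * peak.width))
            a = offset_to_base(boundary, ev.strand, peak.offset - half)
            b = offset_to_base(boundary, ev.strand, peak.offset + half)
            lo, hi = min(a, b), max(a, b) + 1
            sites.append(GenomicInterval(ev.chrom, lo, hi, ev.strand))
    return sites


def background_fraction_for_fold(
    dataset: SyntheticDataset,
    peaks: Sequence[BindingPeakSpec],
    fold: float,
) -> float:
    """Background fraction giving planted sites the requested enrichment.

    With transcribed length T, total planted-site width W, and background
    fraction b, in-site CLIP density relative to the uniform control density
    is b + (1-b) T / W; solving for the target fold gives
    1 - b = (fold - 1) W / (T - W).
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    _, span_lengths, cum = _span_arrays(dataset.genes)
    T = float(cum[-1])
    W = float(sum(len(s) for s in planted_site_intervals(dataset.events, peaks)))
    if W >= T:
        raise ValueError("planted sites cover the whole transcribed span")
    one_minus_b = (fold - 1.0) * W / (T - W)
    if not 0.0 < one_minus_b < 1.0:
        raise ValueError(
            f"target fold {fold} unreachable with site width {W:.0f} over "
            f"transcribed length {T:.0f}"
        )
    return 1.0 - one_minus_b


@dataclass(frozen=True)
class EnrichedSimulation:
    dataset: SyntheticDataset
    clip_tags: list[ClipTag]
    control_tags: list[ClipTag]
    sites: list[GenomicInterval]


def simulate_enriched_dataset(
    seed: int,
    n_genes: int = 50,
    fold: float = 10.0,
    library_size: int = 100_000,
) -> EnrichedSimulation:
    """Known-truth benchmark: one planted enriched site per gene.

    Every gene carries a cassette exon with a single broad binding site
    centered in the downstream intron; the background fraction is solved so
    each site is ``fold``-times enriched over the uniform control library.
    """
    peak = BindingPeakSpec("cassette_5ss", 2500, 600.0, 0.0)
    draft = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        exons_per_gene=(6, 8),
        exon_length=(120, 180),
        intron_length=(6500, 8000),
        cassette_fraction=1.0,
        retained_intron_fraction=0.0,
        motif_prob=0.0,
        peaks=(replace(peak, weight=0.5),),
        background_fraction=0.5,
        clip_library_size=library_size,
        control_library_size=library_size,
    )
    dataset = generate_annotation(draft)
    b = background_fraction_for_fold(dataset, (peak,), fold)
    config = replace(
        draft,
        background_fraction=b,
        peaks=(replace(peak, weight=1.0 - b),),
    )
    dataset = replace(dataset, config=config)
    clip = simulate_clip_library(dataset)
    control = simulate_control_library(dataset)
    sites = planted_site_intervals(dataset.events, config.peaks)
    return EnrichedSimulation(dataset, clip, control, sites)


# ---------------------------------------------------------------------------
# Band intensities
# ---------------------------------------------------------------------------


def simulate_band_intensities(
    true_skip_ratio: float,
    total_intensity: float,
    cv: float,
    n: int,
    seed: int,
) -> list[BandPair]:
    """Noisy two-band gel intensities with a known true skipping ratio.

    Multiplicative lognormal noise with coefficient of variation ``cv`` is
    applied independently to each band's expected intensity; the noise has
    unit mean, so band means are unbiased. ``cv = 0`` is exact.
    """
    if not 0.0 <= true_skip_ratio <= 1.0:
        raise ValueError("true_skip_ratio must be in [0, 1]")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    mu_s = total_intensity * true_skip_ratio
    mu_i = total_intensity * (1.0 - true_skip_ratio)
    if cv == 0:
        factors = np.ones((n, 2))
    else:
        sigma2 = np.log1p(cv * cv)
        factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=(n, 2))
    return [
        BandPair(mu_s * float(f[0]), mu_i * float(f[1]))
        for f in factors
    ]


# ---------------------------------------------------------------------------
# Autoregulation fixture
# ---------------------------------------------------------------------------


def fus_like_fixture() -> tuple[TranscriptModel, str]:
    """A deterministic 15-exon coding transcript with a poison cassette exon.

    Exon 7 (120 nt exons elsewhere; exon 7 is 100 nt, not divisible by 3)
    is constructed so that skipping it shifts the reading frame and the
    first downstream stop codon falls inside the exon-8 segment, more than
    50 nt upstream of the last exon-exon junction — the geometry of a
    splicing factor that routes its own exon-skip isoform into NMD.
    """
    exon_lengths = [120] * 15
    exon_lengths[6] = 100
    total = sum(exon_lengths)  # 1780
    cds_start = 30
    cds_end = 1719  # stop codon at [1716, 1719)
    j6 = sum(exon_lengths[:6])  # 720: transcript start of exon 7
    e7_end = j6 + 100  # 820: transcript start of exon 8
    e8_end = e7_end + 120

    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]

    for attempt in range(200):
        rng = np.random.default_rng(7_001_000 + attempt)
        utr5 = "".join(rng.choice(list("ACGT"), size=cds_start))
        n_codons = (cds_end - cds_start) // 3  # 563
        body = ["ATG"]
        body += [non_stop[i] for i in rng.integers(0, len(non_stop), n_codons - 2)]
        body.append("TAA")
        utr3 = "".join(rng.choice(list("ACGT"), size=total - cds_end))
        seq = list(utr5 + "".join(body) + utr3)

        # Plant the shifted-frame stop: skipped-transcript codons realign at
        # the exon6|exon8 junction (j6), so original position 820 + 3m reads
        # as a codon in the skip isoform. m = 10 puts the stop 30 nt into
        # exon 8.
        plant = e7_end + 30
        seq[plant : plant + 3] = "TAA"
        seq = "".join(seq)

        # Constraint checks (all on the raw sequence, no pipeline code):
        # reference frame must stay stop-free before the annotated stop ...
        ref_clean = all(
            seq[p : p + 3] not in ("TAA", "TAG", "TGA")
            for p in range(cds_start, cds_end - 3, 3)
        )
        # ... and the skip isoform's first stop must be the planted one.
        skipped_seq = seq[:j6] + seq[e7_end:]
        first = next(
            (
                p
                for p in range(cds_start, len(skipped_seq) - 2, 3)
                if skipped_seq[p : p + 3] in ("TAA", "TAG", "TGA")
            ),
            None,
        )
        planted_in_skip = j6 + 30
        if ref_clean and first == planted_in_skip:
            break
    else:  # pragma: no cover - the search space makes this unreachable
        raise RuntimeError("fixture construction failed")

    # Genomic layout: plus strand, 300-nt introns.
    exons = []
    pos = 1000
    for ln in exon_lengths:
        exons.append(GenomicInterval("chrF", pos, pos + ln, "+"))
        pos += ln + 300
    roles = ["constitutive"] * 15
    roles[6] = "cassette"
    model = TranscriptModel(
        transcript_id="tFUSL",
        gene_id="gFUSL",
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
        exon_roles=tuple(roles),
    )
    return model, seq


# ---------------------------------------------------------------------------
# Output directory
# ---------------------------------------------------------------------------


def config_echo(config: SimulationConfig) -> str:
    """Flat key:value echo of the configuration."""
    lines = []
    for name in config.__dataclass_fields__:
        value = getattr(config, name)
        if name == "peaks":
            value = "; ".join(
                f"{p.anchor}{p.offset:+d} width={p.width:g} weight={p.weight:g}"
                for p in value
            )
        lines.append(f"{name}: {value}")
    return "\n".join(lines) + "\n"


def write_dataset(
    dataset: SyntheticDataset,
    clip_tags: Sequence[ClipTag],
    control_tags: Sequence[ClipTag],
    outdir: Path,
) -> dict[str, str]:
    """Write FASTA, GTF, two BED6 libraries, the event TSV, and a config
    echo into ``outdir``; returns a manifest of file name -> sha256."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_fasta(dataset.genome, outdir / "genome.fa")
    cio.write_gtf(dataset.genes, outdir / "annotation.gtf")
    cio.write_bed(clip_tags, outdir / "clip_tags.bed")
    cio.write_bed(control_tags, outdir / "control_tags.bed")
    cio.write_alt_events(dataset.events, outdir / "alt_events.tsv")
    (outdir / "config.txt").write_text(config_echo(dataset.config))
    manifest = {}
    for name in (
        "genome.fa",
        "annotation.gtf",
        "clip_tags.bed",
        "control_tags.bed",
        "alt_events.tsv",
        "config.txt",
    ):
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        manifest[name] = digest
    with open(outdir / "MANIFEST.txt", "w") as fh:
        for name, digest in manifest.items():
            fh.write(f"{digest}  {name}\n")
    return manifest
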