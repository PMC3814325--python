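# clip-splicemap

Analysis pipeline for the computational side of a CLIP-seq study of a
splicing factor that binds the introns flanking cassette exons and represses
a "poison" cassette exon in its own pre-mRNA: binding-site (cluster) calling
against a nonspecific-antibody control library, association of clusters with
alternative-splicing events under a permutation null, position-anchored
normalized complexity maps ("RNA splicing maps"), k-mer motif enrichment,
and splicing quantification coupled to nonsense-mediated-decay (AS-NMD)
prediction.

Real CLIP libraries are large and lab-specific, so the package ships a
first-class synthetic-data generator that emulates the statistical structure
every stage assumes — genes with cassette exons flanked by constitutive
exons, tag pileups at defined offsets from exon boundaries over a uniform
background, a background-only control library, planted sequence motifs, and
noisy two-band gel intensities with a known true skipping ratio. Every
claim the test suite makes is a recovery or calibration statement against
that planted truth.

## The statistics at the core

**Cluster calling.** After exact-coordinate deduplication, overlapping
same-strand tags are chained into candidate clusters. A cluster with *c*
CLIP tags and *k* control tags over its extent is scored with a conditional
binomial test: under the null, each of the *c + k* tags belongs to the CLIP
library with probability π = N_clip/(N_clip + N_ctrl), so
p = P(X ≥ c), X ~ Binomial(c + k, π), and
fold = ((c + 0.5)/N_clip) / ((k + 0.5)/N_ctrl).
Benjamini–Hochberg control marks clusters with q ≤ 0.05 significant.

**Event association.** A cluster is associated with an alternative-splicing
event if it overlaps, on the same strand, the event or its immediate
flanking introns/exons. Observed per-category event counts are compared
with 100 trials in which every cluster is relocated (length- and
strand-preserving) uniformly over the transcribed spans of expressed genes:
z = (observed − mean)/sd over trials.

**Normalized complexity map.** For events anchored at a splice-site
boundary, value(d) is the fraction of events with ≥ 1 same-strand tag
covering the base at transcript-oriented offset d ∈ [−500, +500]; each
event contributes at most 1 per offset regardless of read depth. The
control averages 100 random same-size sets of constitutive exons from
expressed genes. Peaks are contiguous excursions of the smoothed
arcsine-√-standardized exceedance above z = 3.

**Motifs.** Overlapping k-mer windows (k ∈ {5, 6}) in cluster RNA sequences
are tested against a letter-shuffled (or genome-sampled) background with a
one-sided binomial test and BH correction.

**AS-NMD.** Skipping an internal exon whose length is not divisible by 3
shifts the reading frame; translation is scanned to the first stop codon,
and a transcript is an NMD substrate when that premature stop sits more
than 50 nt upstream of the last exon–exon junction (the 50-nt rule).
Gel quantification: skipping ratio = skipped/(skipped + included) band
intensity, per-isoform reduction = treated/mock, and qRT-PCR relative
expression = 2^−ΔΔCt.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed 1 throughout; each step writes its tables under `results/`):

```bash
python analysis/01_simulate.py          # genome, annotation, tag libraries
python analysis/02_call_clusters.py     # enriched clusters vs control
python analysis/03_classify_regions.py  # genomic region classes
python analysis/04_associate_events.py  # event association + permutation z
python analysis/05_splicing_map.py      # normalized complexity map + peaks
python analysis/06_motifs.py            # k-mer enrichment
python analysis/07_nmd_quantify.py      # AS-NMD fixture + gel formulas
```

Representative output (seed 1): `02` finds 1534 candidate clusters among
20 000 CLIP tags, 120 significant at FDR ≤ 0.05, all intronic — binding was
planted in introns around the 30 cassette exons. `04` prints

```
       category  observed  expected_mean  expected_sd         z
  cassette_exon        30           8.93     2.682736  7.853923
retained_intron         0           2.40     1.279204 -1.876166
```

— every cassette exon is recovered as bound (z ≈ 7.9) while the unbound
retained-intron category stays inside the null band. `05` calls six map
peaks; the four planted ones appear at +113/+409 (cassette 5'ss), −143
(cassette 3'ss) and +312 (upstream-exon 5'ss), within ~13 nt of the planted
offsets (the remaining two are the same physical peaks seen across the
short cassette exon from the neighboring anchor). `06` ranks the planted
hexamer first: `CAGGUU fold=24.64 q=2.1e-81`. `07` shows the fixture's
exon-7-skip isoform is frameshifted with a premature stop 30 nt into the
exon-8 segment, 810 nt upstream of the last junction — an NMD substrate —
and recovers gel skipping ratios to within 0.001 at 10 % band noise.

The same stages are exposed as a CLI (`clip-splicemap simulate /
call-clusters / classify-regions / associate / rnamap / motifs / quantify /
nmd / all`); `clip-splicemap all --seed 1 --out run/` reproduces the whole
chain in one command.

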