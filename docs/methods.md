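# Methods

This note records the models, parameter choices, and numerical decisions
behind the pipeline, and what the synthetic benchmarks do and do not show.

## Coordinates and strand handling

All internal coordinates are 0-based half-open (BED convention); GTF's
1-based inclusive coordinates are converted once, at the file boundary.
Overlap is strand-aware everywhere: CLIP is a stranded protocol, so a tag
never counts toward a feature on the opposite strand. Transcript
coordinates count nucleotides from the transcript 5' end; offsets from
splice-site anchors are transcript-oriented (positive toward the 3' end),
so on minus-strand genes they run toward decreasing genomic coordinates.
Offset 0 is the first base on the 3' side of the anchor boundary.

## Cluster calling

Deduplication keeps one tag per (chrom, start, end, strand); the survivor
is the lexicographically smallest tag id, making the result independent of
input order. Candidate clusters chain same-strand tags with at least one
shared base (half-open semantics: abutting tags do not merge); the default
`min_depth = 2` reflects that a binding site needs overlapping tags —
singletons never form a cluster.

The enrichment model is a conditional two-library binomial test. Given
unique library sizes N_clip and N_ctrl, and a cluster with c CLIP and k
control tags over its extent, the test conditions on the total c + k and
asks whether the CLIP share exceeds π = N_clip/(N_clip + N_ctrl):
p = P(X ≥ c) for X ~ Binomial(c + k, π). It is exact at small counts and
fully specified — deliberately so, since peak-finder internals are
typically opaque. Fold enrichment carries a 0.5 pseudocount on both rates
so k = 0 gives a finite value. Control tags are counted by interval
overlap with the final cluster extent rather than clustered themselves:
the control library estimates background density, it is not a peak set.
FDR control is Benjamini–Hochberg (the field default where only "FDR" is
specified); ties in p are resolved by the stable position sort of the
output, so reports are byte-reproducible.

Degenerate inputs: empty libraries are data errors; c = 0 is refused by
the scorer; π → 1 (negligible control library) drives p → 1, so nothing
can be called against a vanishing control.

## Event association and the permutation null

The association region of an event is the contiguous union of the event
interval with its immediate flanking introns and exons. Flanking introns
are optional components: a retained-intron event *is* the intron, so its
exons abut it directly and the union rule is unchanged. An event
associated through several clusters counts once — the statistic is the
number of associated events per category.

The null relocates each cluster, preserving length, to a uniformly random
transcribed base of the expressed-gene set (the cluster adopts the host
gene's strand and must fit within its span; positions are drawn uniformly
over the union of spans, i.e. genes are hit proportionally to their
length). This matches the uniform-background tag model exactly, which is
what makes the z-scores calibrated under uniform placement: a
uniform-per-gene relocation would bias expected counts whenever spans
differ. Trials use the sample (n−1) standard deviation; with sd = 0 or a
single trial, z is reported as undefined rather than computed.

Note the planted simulations show a *negative* z for categories without
planted binding (retained introns, z ≈ −1.6 under the default conditions):
when real binding concentrates at cassette exons, random relocation
over-predicts hits everywhere else. That mild depletion is a genuine
property of the statistic, not a bug.

## Normalized complexity map

value(d) is the fraction of events with ≥ 1 same-strand covering tag at
transcript-oriented offset d ∈ [−window, +window] (window default 500 nt),
each event contributing at most 1 per offset. This per-event saturation is
the normalization: deep and shallow events weigh equally, values live on a
common 0–1 axis, and duplicating one event's tags k-fold changes nothing
(tested exactly). The four anchors (upstream-exon 5'ss, cassette 3'ss,
cassette 5'ss, downstream-exon 3'ss) are computed separately and reported
side by side in that order. Offsets report the coverage of whatever
sequence lies at that genomic position; offsets beyond a short exon's body
are not masked — the peaks of interest are intronic, and positions without
tags contribute 0. Offsets beyond the chromosome end simply have no tags.

The control profiles random sets of internal constitutive exons from
expressed genes at their own 3'/5' splice sites (sets of `set_size` drawn
without replacement within a set, independently across `n_sets = 100`
sets); a map anchored at a 5'ss is compared against the control's 5'ss
profile, and likewise for 3'ss.

**Exceedance.** The observed-minus-control difference is standardized on
the arcsine-square-root scale, T(v) = asin(√v):

    z(d) = (T(value) − mean_sets T(set)) /
           (sd_sets T(set) · sqrt(1 + set_size / n_events))

Two deliberate choices: (1) the transform stabilizes the variance of
binomial proportions — on the raw scale, sparse coverage makes per-offset
covered-event counts near-Poisson with a heavy upper tail, and a map scans
thousands of offsets, so raw-scale z produces spurious threshold crossings
under a pure background; (2) the √(1 + set_size/n_events) factor is the
null sd of the difference between two independent set-level profiles (the
observed set and one control set), which is conservative relative to
comparing against the control mean alone. Smoothing (centered moving
average, default width 11, edges renormalized) is applied to each control
set before the across-set sd so the z stays correctly standardized; the sd
is floored at 1/(2·set_size) (about half a count on the transformed scale)
to avoid blow-ups in tag-free stretches. Measured under background-only
libraries, the map-wide maximum exceedance is ~2.0–2.5; planted peaks
reach z ≈ 9–13.

**Peak reporting.** Each maximal contiguous excursion above the z
threshold (default 3) is reported once, at its exceedance-weighted
centroid. The centroid was chosen over the excursion argmax after
measurement: at realistic depths the excursion top is noise-flattened and
its argmax wanders by tens of nucleotides between seeds, while the
centroid is stable to within ~15 nt of the planted offset. Reported peak
positions carry a small systematic shift of about half a tag length
downstream of the planted tag-start offset, because coverage extends 3' of
each tag's 5' end.

## Motif enrichment

Overlapping windows are counted (a GGGUGU run contains overlapping GGU
hits), making the window-accounting identity Σ_kmers hits = Σ_seqs
(len − k + 1) exact. The background rate carries a (b + 0.5)/(n + 1)
pseudocount so k-mers absent from the background get finite fold; the test
is the same one-sided binomial tail as cluster scoring, BH-corrected over
all k-mers with ≥ 1 target hit. The default background is the
letter-shuffle of each target (length and mononucleotide composition
preserved, 10 shuffles per target); a genomic mode draws length-matched
fragments, strand random, from a supplied assembly. Position-weight-matrix
discovery and dinucleotide-preserving shuffles are out of scope: the
claims this statistic supports are k-mer-level.

## Splicing quantification and AS-NMD

The closed-form gel/qPCR formulas are implemented exactly as stated
(skipping ratio, treated/mock reduction, 2^−ΔΔCt). `skip_exon` removes an
internal exon, re-splices the sequence, and records the removed length;
the start codon must lie upstream of the removed exon, and downstream
coordinates (including the annotated stop) shift by the deletion.
`predict_nmd` scans codons from the start codon to the first stop
(standard nuclear code; no selenocysteine) and applies the 50-nt
exon-junction rule — NMD substrate iff a premature stop's first base lies
more than 50 nt (configurable) upstream of the last exon–exon junction.
A transcript with no in-frame stop is flagged `no_stop` and never called a
substrate. The bundled fixture is a deterministic 15-exon coding
transcript whose 100-nt seventh exon breaks frame when skipped, placing
the first stop 30 nt into the eighth exon's segment; it is constructed by
a seeded search that verifies all constraints before returning, so no
run-time randomness is involved.

## Synthetic data: what it emulates, and what it does not

The generator is a pure function of (config, seed). Genes are laid out on
~10-gene chromosomes with alternating strands; each gene has 6–8 exons of
120–180 nt separated by 1.2–1.8 kb introns, one transcript, and a CDS
whose length is a multiple of 3. Cassette exons are internal with internal
constitutive flanks, so every cassette event is constitutively flanked by
construction. Tag 5' ends follow the signal model — background tags
uniform over transcribed spans, signal tags Normal(anchor + offset, width)
clipped to the host intron/exon — and tags extend 3' by an independently
drawn length. The motif (default CAGGUU, planted as DNA in transcript
orientation) is written at each peak's central offset with probability 0.6
per (event, peak).

Two named study conditions: the **default** configuration (120 genes,
cassette fraction 0.25, retained-intron fraction 0.1, 20k-tag libraries,
tags 20–30 nt, background fraction 0.5, the four-peak geometry with the
+100 peak carrying the most mass) drives cluster calling, region classes,
association, and motifs; the **map** configuration (cassette fraction 0.5
→ 60 events, 4k-tag libraries of 15–25 nt tags) keeps per-offset map
values in the informative middle of the 0–1 axis rather than saturating
near peaks. The **enriched-sites** benchmark (50 genes, one broad site per
gene centered in a 6.5–8 kb downstream intron) solves the background
fraction from the target fold — 1 − b = (F−1)·W/(T−W) for total site
width W and transcribed length T — so each planted site has CLIP density
F× the uniform control density.

Not modeled: sequencing errors, PCR duplicates beyond exact coordinates,
expression heterogeneity between genes, spliced (gapped) tag alignments,
crosslink-site truncation, replicates. Passing benchmarks therefore show
that the statistics recover planted structure under their own assumptions
at realistic sizes; they do not show robustness to the many ways real
libraries violate uniform background and independent tags.

## Problem sizes

The benchmark scenarios were sized to be informative while remaining
desk-scale: 100k-tag libraries over ~2.3 Mb of transcribed span for
cluster recovery (5 seeds), 20-seed null calibrations at 20k tags, 100
permutation trials and 100 control sets throughout, 200 fuzzed transcripts
for the NMD oracle, and 1000 simulated gels per skipping-ratio truth. The
full test suite runs in well under a minute; the acceptance script in
about fifteen seconds.
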