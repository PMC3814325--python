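"""Genomic-region classification of CLIP clusters.

Each cluster receives exactly one label from {cds, 5utr, 3utr, ncrna,
intron, intergenic}. When a cluster overlaps several annotated features the
highest-precedence label wins (cds > 5utr > 3utr > ncrna > intron >
intergenic); when several genes overlap, the transcript giving the
highest-precedence label wins. Overlap means at least one shared base on the
same strand. "ncrna" is any exonic sequence of a transcript without a CDS.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .coords import transcript_to_genomic_segments
from .models import GeneModel, GenomicInterval, TranscriptModel

REGION_LABELS = ("cds", "5utr", "3utr", "ncrna", "intron", "intergenic")

_PRECEDENCE = {label: rank for rank, label in enumerate(REGION_LABELS)}


def _transcript_feature_segments(t: TranscriptModel):
    """Yield (label, genomic_start, genomic_end) for one transcript."""
    if t.coding:
        if t.cds_start > 0:
            for gs, ge in transcript_to_genomic_segments(t, 0, t.cds_start):
                yield "5utr", gs, ge
        for gs, ge in transcript_to_genomic_segments(t, t.cds_start, t.cds_end):
            yield "cds", gs, ge
        if t.cds_end < t.length:
            for gs, ge in transcript_to_genomic_segments(t, t.cds_end, t.length):
                yield "3utr", gs, ge
    else:
        for exon in t.exons:
            yield "ncrna", exon.start, exon.end
    for a, b in zip(t.exons, t.exons[1:]):
        if a.end < b.start:
            yield "intron", a.end, b.start


class RegionIndex:
    """Strand-aware interval index of annotated feature segments."""

    def __init__(self, gene_models: Sequence[GeneModel]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for gene in gene_models:
            for t in gene.transcripts:
                key = (t.chrom, t.strand)
                tree = self._trees.setdefault(key, IntervalTree())
                for label, gs, ge in _transcript_feature_segments(t):
                    tree.addi(gs, ge, label)

    def classify(self, interval: GenomicInterval) -> str:
        tree = self._trees.get((interval.chrom, interval.strand))
        if tree is None:
            return "intergenic"
        hits = tree.overlap(interval.start, interval.end)
        if not hits:
            return "intergenic"
        return min((h.data for h in hits), key=_PRECEDENCE.__getitem__)


def classify_cluster_region(
    cluster_interval: GenomicInterval, gene_models: Sequence[GeneModel]
) -> str:
    """Region label for a single cluster (builds a throwaway index)."""
    return RegionIndex(gene_models).classify(cluster_interval)


def classify_many(
    intervals: Iterable[GenomicInterval], gene_models: Sequence[GeneModel]
) -> list[str]:
    index = RegionIndex(gene_models)
    return [index.classify(iv) for iv in intervals]


def region_counts(labels: Iterable[str]) -> dict[str, int]:
    """Label -> count, with every label present (zeros included)."""
    counts = Counter(labels)
    return {label: counts.get(label, 0) for label in REGION_LABELS}
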