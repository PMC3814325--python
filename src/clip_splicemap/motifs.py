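"""k-mer motif enrichment in cluster sequences over randomized background.

A defined-statistic motif scan: count every overlapping k-mer window in the
cluster (target) sequences and in a randomized background, then test each
k-mer's target rate against the background rate with a one-sided binomial
test and BH correction. Overlapping windows are counted, so a run like
GGGUGU can contain overlapping hits; the window-accounting invariant
(sum of hits over k-mers = sum over sequences of len-k+1) depends on this.

The default background shuffles each target sequence (preserving length and
mononucleotide composition); a genomic mode draws length-matched random
fragments from a supplied genome, strand random, mirroring background draws
from a reference assembly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .clusters import bh_fdr
from .errors import DataError
from .models import ClipCluster

_COMPLEMENT_RNA = str.maketrans("ACGU", "UGCA")
_DNA_TO_RNA = str.maketrans("Tt", "Uu")


@dataclass(frozen=True)
class KmerStat:
    kmer: str
    target_hits: int
    target_positions: int
    background_hits: int
    background_positions: int
    fold: float
    p_value: float
    q_value: float


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Sequence slice from a dict of strings or a pyfaidx.Fasta."""
    seq = genome[chrom][start:end]
    return str(seq)


def extract_cluster_sequences(
    clusters: Sequence[ClipCluster], genome
) -> list[str]:
    """Strand-aware RNA sequences of clusters (minus strand reverse-
    complemented, T->U)."""
    out = []
    for cl in clusters:
        iv = cl.interval
        contig_len = len(genome[iv.chrom])
        if iv.end > contig_len:
            raise DataError(
                f"cluster {cl.cluster_id} extends beyond contig "
                f"{iv.chrom} ({iv.end} > {contig_len})"
            )
        dna = _fetch(genome, iv.chrom, iv.start, iv.end).upper()
        rna = dna.translate(_DNA_TO_RNA)
        if iv.strand == "-":
            rna = rna.translate(_COMPLEMENT_RNA)[::-1]
        out.append(rna)
    return out


def select_high_depth_subregions(
    clusters: Sequence[ClipCluster], min_center_depth: int = 100
) -> list[ClipCluster]:
    """Clusters with a peak tag depth strictly over the threshold."""
    return [cl for cl in clusters if cl.peak_depth > min_center_depth]


def make_background(
    target_seqs: Sequence[str],
    n_per_target: int = 10,
    mode: str = "shuffle",
    seed: int = 0,
    genome=None,
) -> list[str]:
    """Randomized background sequences.

    ``shuffle``: per target, ``n_per_target`` independent uniform
    permutations of its letters. ``genomic``: length-matched draws from the
    supplied genome, strand random.
    """
    if not target_seqs:
        raise DataError("background generation needs target sequences")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    if mode == "shuffle":
        for seq in target_seqs:
            letters = np.array(list(seq))
            for _ in range(n_per_target):
                out.append("".join(letters[rng.permutation(len(letters))]))
        return out
    if mode == "genomic":
        if genome is None:
            raise ValueError("genomic background mode requires a genome")
        chroms = sorted(genome.keys()) if hasattr(genome, "keys") else sorted(
            r.name for r in genome
        )
        sizes = np.array([len(genome[c]) for c in chroms], dtype=np.int64)
        for seq in target_seqs:
            ln = len(seq)
            for _ in range(n_per_target):
                ci = int(rng.integers(0, len(chroms)))
                if sizes[ci] < ln:
                    raise DataError("contig shorter than a target sequence")
                start = int(rng.integers(0, sizes[ci] - ln + 1))
                rna = _fetch(genome, chroms[ci], start, start + ln).upper()
                rna = rna.translate(_DNA_TO_RNA)
                if rng.random() < 0.5:
                    rna = rna.translate(_COMPLEMENT_RNA)[::-1]
                out.append(rna)
        return out
    raise ValueError(f"unknown background mode {mode!r}")


def _count_windows(seqs: Sequence[str], k: int) -> tuple[Counter, int]:
    counts: Counter = Counter()
    positions = 0
    for seq in seqs:
        n = len(seq) - k + 1
        if n <= 0:
            continue
        positions += n
        for i in range(n):
            counts[seq[i : i + k]] += 1
    return counts, positions


def kmer_enrichment(
    target_seqs: Sequence[str],
    background_seqs: Sequence[str],
    k: int,
) -> list[KmerStat]:
    """Enrichment statistics for every k-mer with >=1 target hit.

    The background rate carries a 0.5/(n+1) pseudocount so k-mers absent
    from the background get a finite fold. Results are sorted by p-value,
    then descending fold.
    """
    if k not in (5, 6):
        raise ValueError("motif length k must be 5 or 6")
    if not target_seqs:
        raise DataError("k-mer enrichment needs target sequences")
    t_counts, t_positions = _count_windows(target_seqs, k)
    if t_positions == 0:
        raise DataError("no target sequence is long enough to hold a k-mer")
    b_counts, b_positions = _count_windows(background_seqs, k)

    kmers = sorted(t_counts)
    t_hits = np.array([t_counts[m] for m in kmers], dtype=np.int64)
    b_hits = np.array([b_counts.get(m, 0) for m in kmers], dtype=np.int64)
    rate_t = t_hits / t_positions
    rate_b = (b_hits + 0.5) / (b_positions + 1)
    fold = rate_t / rate_b
    p = np.minimum(sps.binom.sf(t_hits - 1, t_positions, rate_b), 1.0)
    q = bh_fdr(p)

    stats = [
        KmerStat(
            kmer=m,
            target_hits=int(t_hits[i]),
            target_positions=t_positions,
            background_hits=int(b_hits[i]),
            background_positions=b_positions,
            fold=float(fold[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
        )
        for i, m in enumerate(kmers)
    ]
    stats.sort(key=lambda s: (s.p_value, -s.fold, s.kmer))
    return stats
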