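"""Readers and writers for the standard formats the pipeline touches.

BED6 for tags and clusters, GTF for annotation, FASTA for genome sequence,
and TSV (tab-separated, header row, UTF-8) for event tables and reports.
Internal coordinates are always 0-based half-open; GTF's 1-based inclusive
coordinates are converted at this boundary and nowhere else.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .coords import cds_genomic_segments, genomic_to_transcript
from .errors import BedFormatError, DataError
from .models import (
    ALT_CATEGORIES,
    AltEvent,
    ClipCluster,
    ClipTag,
    GeneModel,
    GenomicInterval,
    STRANDS,
    TranscriptModel,
)

# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def read_bed(path: Union[str, Path], library: str = "clip") -> list[ClipTag]:
    """Read a 6-column BED file of tags.

    Coordinates are kept 0-based half-open as in the file. Malformed lines
    raise :class:`BedFormatError` naming the 1-based line number; a missing
    strand column is a hard error because every downstream stage is
    strand-aware.
    """
    tags: list[ClipTag] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise BedFormatError(
                    f"{path}, line {lineno}: expected 6 BED columns "
                    f"(chrom, start, end, name, score, strand), got "
                    f"{len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from exc
            if strand not in STRANDS:
                raise BedFormatError(
                    f"{path}, line {lineno}: invalid strand {strand!r}"
                )
            if not 0 <= start < end:
                raise BedFormatError(
                    f"{path}, line {lineno}: invalid interval "
                    f"{start}-{end} (need 0 <= start < end)"
                )
            tags.append(
                ClipTag(
                    GenomicInterval(chrom, start, end, strand),
                    library=library,
                    tag_id=name,
                )
            )
    return tags


def _bed_record(item) -> tuple[GenomicInterval, str, int]:
    if isinstance(item, ClipTag):
        return item.interval, item.tag_id or ".", 0
    if isinstance(item, ClipCluster):
        q = item.q_value
        score = 0
        if q == q and q > 0:  # not NaN
            score = min(1000, round(-10.0 * math.log10(q)))
        return item.interval, item.cluster_id, score
    if isinstance(item, GenomicInterval):
        return item, ".", 0
    raise TypeError(f"cannot write {type(item).__name__} as BED")


def write_bed(items: Iterable, path: Union[str, Path]) -> None:
    """Write tags, clusters, or bare intervals as BED6.

    Cluster scores encode the q-value as ``min(1000, round(-10*log10 q))``.
    """
    with open(path, "w") as fh:
        for item in items:
            iv, name, score = _bed_record(item)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t"
                f"{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(
    sequences: dict[str, str], path: Union[str, Path], width: int = 60
) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------

#: GTF attribute key carrying the per-exon role flag; absent -> "other".
EXON_ROLE_ATTR = "exon_role"


def write_gtf(genes: Sequence[GeneModel], path: Union[str, Path]) -> None:
    """Write gene models as GTF (gene/transcript/exon/CDS features)."""

    def attrs(**kv) -> str:
        return " ".join(f'{k} "{v}";' for k, v in kv.items())

    with open(path, "w") as fh:
        for gene in genes:
            span = gene.span
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "clip_splicemap",
                        "gene",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs(
                            gene_id=gene.gene_id,
                            expressed=int(gene.expressed),
                        ),
                    ]
                )
                + "\n"
            )
            for t in gene.transcripts:
                tspan = t.span()
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "clip_splicemap",
                            "transcript",
                            str(tspan.start + 1),
                            str(tspan.end),
                            ".",
                            t.strand,
                            ".",
                            attrs(gene_id=gene.gene_id, transcript_id=t.transcript_id),
                        ]
                    )
                    + "\n"
                )
                for exon, role in zip(t.exons, t.exon_roles):
                    fh.write(
                        "\t".join(
                            [
                                t.chrom,
                                "clip_splicemap",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                t.strand,
                                ".",
                                attrs(
                                    gene_id=gene.gene_id,
                                    transcript_id=t.transcript_id,
                                    exon_role=role,
                                ),
                            ]
                        )
                        + "\n"
                    )
                if t.coding:
                    for gs, ge in cds_genomic_segments(t):
                        fh.write(
                            "\t".join(
                                [
                                    t.chrom,
                                    "clip_splicemap",
                                    "CDS",
                                    str(gs + 1),
                                    str(ge),
                                    ".",
                                    t.strand,
                                    "0",
                                    attrs(
                                        gene_id=gene.gene_id,
                                        transcript_id=t.transcript_id,
                                    ),
                                ]
                            )
                            + "\n"
                        )


def read_annotation(path: Union[str, Path]) -> list[GeneModel]:
    """Read a GTF with gene/transcript/exon/CDS features into gene models.

    1-based inclusive GTF coordinates are converted to 0-based half-open.
    The CDS is re-expressed in transcript coordinates; a transcript whose
    CDS is not contained in its exons, or with no exons at all, is a
    :class:`DataError`. Exon roles come from the ``exon_role`` attribute
    (default ``other``); gene expression from the ``expressed`` attribute
    (default true).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes["gene_id"][0]
        expressed = True
        if "expressed" in g.attributes:
            expressed = g.attributes["expressed"][0] not in ("0", "false", "False")
        transcripts: list[TranscriptModel] = []
        for t in db.children(g, featuretype="transcript"):
            tid = t.attributes["transcript_id"][0]
            exons = []
            roles = []
            for e in db.children(t, featuretype="exon", order_by="start"):
                exons.append(
                    GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                )
                role = e.attributes.get(EXON_ROLE_ATTR, ["other"])[0]
                roles.append(role)
            if not exons:
                raise DataError(f"transcript {tid} has no exons")
            cds = [
                GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
                for c in db.children(t, featuretype="CDS", order_by="start")
            ]
            cds_start = cds_end = None
            if cds:
                for seg in cds:
                    if not any(
                        ex.start <= seg.start and seg.end <= ex.end
                        for ex in exons
                    ):
                        raise DataError(
                            f"transcript {tid}: CDS segment "
                            f"{seg.start}-{seg.end} not contained in exons"
                        )
                model_wo_cds = TranscriptModel(
                    tid, gene_id, tuple(exons), exon_roles=tuple(roles)
                )
                total = sum(len(seg) for seg in cds)
                if t.strand == "+":
                    first_base = min(seg.start for seg in cds)
                else:
                    first_base = max(seg.end for seg in cds) - 1
                cds_start = genomic_to_transcript(model_wo_cds, first_base)
                cds_end = cds_start + total
            transcripts.append(
                TranscriptModel(
                    tid,
                    gene_id,
                    tuple(exons),
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exon_roles=tuple(roles),
                )
            )
        genes.append(GeneModel(gene_id, tuple(transcripts), expressed=expressed))
    return genes


# ---------------------------------------------------------------------------
# Alternative-splicing event tables
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "event_id",
    "category",
    "chrom",
    "strand",
    "event_start",
    "event_end",
    "up_exon_start",
    "up_exon_end",
    "up_intron_start",
    "up_intron_end",
    "down_intron_start",
    "down_intron_end",
    "down_exon_start",
    "down_exon_end",
    "host_gene",
    "flanking_constitutive",
]


def write_alt_events(events: Sequence[AltEvent], path: Union[str, Path]) -> None:
    rows = []
    for ev in events:
        def pair(iv: Optional[GenomicInterval]):
            return (iv.start, iv.end) if iv is not None else (None, None)

        uis, uie = pair(ev.upstream_intron)
        dis, die = pair(ev.downstream_intron)
        rows.append(
            {
                "event_id": ev.event_id,
                "category": ev.category,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "event_start": ev.event_interval.start,
                "event_end": ev.event_interval.end,
                "up_exon_start": ev.upstream_exon.start,
                "up_exon_end": ev.upstream_exon.end,
                "up_intron_start": uis,
                "up_intron_end": uie,
                "down_intron_start": dis,
                "down_intron_end": die,
                "down_exon_start": ev.downstream_exon.start,
                "down_exon_end": ev.downstream_exon.end,
                "host_gene": ev.host_gene,
                "flanking_constitutive": int(ev.flanking_constitutive),
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alt_events(path: Union[str, Path]) -> list[AltEvent]:
    """Read an event table (one event per row, columns mirroring AltEvent).

    Rows with a category outside the known set are skipped; a single
    ``UserWarning`` reports how many were dropped. Component intervals that
    do not abut raise :class:`DataError` naming the event.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing event columns {sorted(missing)}")
    events: list[AltEvent] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        if row.category not in ALT_CATEGORIES:
            n_skipped += 1
            continue
        chrom, strand = row.chrom, row.strand

        def iv(start, end) -> Optional[GenomicInterval]:
            if pd.isna(start) or pd.isna(end):
                return None
            return GenomicInterval(chrom, int(start), int(end), strand)

        try:
            events.append(
                AltEvent(
                    event_id=str(row.event_id),
                    category=row.category,
                    event_interval=iv(row.event_start, row.event_end),
                    upstream_exon=iv(row.up_exon_start, row.up_exon_end),
                    downstream_exon=iv(row.down_exon_start, row.down_exon_end),
                    upstream_intron=iv(row.up_intron_start, row.up_intron_end),
                    downstream_intron=iv(row.down_intron_start, row.down_intron_end),
                    host_gene=str(row.host_gene),
                    flanking_constitutive=bool(row.flanking_constitutive),
                )
            )
        except ValueError as exc:
            raise DataError(f"{path}: event {row.event_id}: {exc}") from exc
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} rows with unknown event categories",
            stacklevel=2,
        )
    return events


# ---------------------------------------------------------------------------
# Cluster report TSV
# ---------------------------------------------------------------------------

_CLUSTER_COLUMNS = [
    "cluster_id",
    "chrom",
    "start",
    "end",
    "strand",
    "clip_count",
    "control_count",
    "peak_depth",
    "fold",
    "p",
    "q",
    "significant",
]


def write_clusters_tsv(
    clusters: Sequence[ClipCluster],
    path: Union[str, Path],
    provenance: Optional[str] = None,
) -> None:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "strand": c.interval.strand,
            "clip_count": c.clip_count,
            "control_count": c.control_count,
            "peak_depth": c.peak_depth,
            "fold": c.fold_enrichment,
            "p": c.p_value,
            "q": c.q_value,
            "significant": int(c.significant),
        }
        for c in clusters
    ]
    df = pd.DataFrame(rows, columns=_CLUSTER_COLUMNS)
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        if provenance:
            fh.write(f"# {provenance}\n")


def read_clusters_tsv(path: Union[str, Path]) -> list[ClipCluster]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ClipCluster(
            cluster_id=str(r.cluster_id),
            interval=GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
            clip_count=int(r.clip_count),
            control_count=int(r.control_count),
            peak_depth=int(r.peak_depth),
            fold_enrichment=float(r.fold),
            p_value=float(r.p),
            q_value=float(r.q),
            significant=bool(r.significant),
        )
        for r in df.itertuples(index=False)
    ]
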