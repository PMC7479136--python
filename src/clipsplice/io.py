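"""Readers/writers for the pipeline's on-disk dialects, plus expression summaries.

Dialects
--------
* annotation: GTF 2.2, 1-based closed coordinates (converted to the internal
  0-based half-open convention on read);
* genome: plain FASTA;
* peaks: BED6, score column = round(fold_enrichment * 100);
* junctions: TSV with columns chrom, donor_end, acceptor_start, strand,
  count, sample — donor_end/acceptor_start are the genomic left/right ends
  of the intron in 0-based coordinates (on '-' strand genes the biological
  donor is the acceptor_start side);
* coverage: bedGraph-like TSV (chrom, start, end, depth), run-length encoded;
* gene counts / truth / result tables: plain TSV.

All tabular readers accept gzip-compressed files (pandas inference); the GTF
reader also accepts a ``.gz`` path.
"""

from __future__ import annotations

import gzip
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .models import GeneModel, Interval, Transcript

JUNCTION_COLUMNS = ["chrom", "donor_end", "acceptor_start", "strand", "count", "sample"]
PEAK_COLUMNS = ["chrom", "start", "end", "name", "fold_enrichment", "strand"]

LOG2FC_PSEUDOCOUNT = 0.1  # FPKM pseudocount bounding fold changes at zero expression


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------

def write_annotation(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/transcript/exon/CDS features in GTF (1-based closed)."""
    lines = []
    for g in sorted(models, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
        attrs_g = f'gene_id "{g.gene_id}";'
        lines.append(_gtf_line(g.chrom, "gene", g.span, g.strand, attrs_g))
        for t in g.transcripts:
            attrs_t = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            lines.append(_gtf_line(g.chrom, "transcript", t.span, g.strand, attrs_t))
            for e in t.exons:
                lines.append(_gtf_line(g.chrom, "exon", e, g.strand, attrs_t))
            if t.cds is not None:
                for e in t.exons:
                    if e.start < t.cds.end and e.end > t.cds.start:
                        cds_part = Interval(
                            max(e.start, t.cds.start), min(e.end, t.cds.end)
                        )
                        lines.append(_gtf_line(g.chrom, "CDS", cds_part, g.strand, attrs_t))
    Path(path).write_text("\n".join(lines) + "\n")


def _gtf_line(chrom: str, feature: str, iv: Interval, strand: str, attrs: str) -> str:
    # GTF is 1-based closed: [start+1, end]
    return "\t".join(
        [chrom, "clipsplice", feature, str(iv.start + 1), str(iv.end), ".", strand, ".", attrs]
    )


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Parse a GTF into gene models (internal 0-based half-open coordinates).

    Rejects transcripts with overlapping exons and records with unknown
    strand, naming the offending identifier.
    """
    path = Path(path)
    if path.suffix == ".gz":
        text = gzip.open(path, "rt").read()
    else:
        text = path.read_text()
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes["gene_id"][0]
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene_id}: unknown strand {gene.strand!r}")
        transcripts = []
        for tr in db.children(gene, featuretype="transcript"):
            tid = tr.attributes["transcript_id"][0]
            exons = [
                Interval(e.start - 1, e.end)
                for e in db.children(tr, featuretype="exon", order_by="start")
            ]
            cds_parts = [
                Interval(c.start - 1, c.end)
                for c in db.children(tr, featuretype="CDS", order_by="start")
            ]
            cds = (
                Interval(min(c.start for c in cds_parts), max(c.end for c in cds_parts))
                if cds_parts
                else None
            )
            try:
                transcripts.append(Transcript(tid, exons, cds))
            except ValueError as err:
                raise ValueError(str(err)) from None
        models.append(GeneModel(gene_id, gene.seqid, gene.strand, transcripts))
    return models


# ---------------------------------------------------------------------------
# Peaks (BED6)
# ---------------------------------------------------------------------------

def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write a peak table as BED6 with score = round(fold_enrichment * 100)."""
    bed = peaks.copy()
    bed["score"] = (bed["fold_enrichment"] * 100).round().astype(int)
    bed[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_peaks(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    bed["fold_enrichment"] = bed["score"] / 100.0
    return bed[PEAK_COLUMNS]


# ---------------------------------------------------------------------------
# Junction tables
# ---------------------------------------------------------------------------

def write_junctions(junctions: pd.DataFrame, path: str | Path) -> None:
    junctions[JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_junctions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction table missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("negative junction counts")
    return df


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Per-base depth over each chromosome, for one sample/library."""

    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.arrays[chrom][start:end]

    def mean(self, chrom: str, start: int, end: int) -> float:
        seg = self.depth(chrom, start, end)
        return float(seg.mean()) if seg.size else math.nan

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack({c: a * factor for c, a in self.arrays.items()})

    def to_bedgraph(self, path: str | Path) -> None:
        """Run-length encoded bedGraph-like TSV (chrom, start, end, depth)."""
        with open(path, "w") as fh:
            for chrom in sorted(self.arrays):
                arr = self.arrays[chrom]
                if arr.size == 0:
                    continue
                breaks = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [arr.size]))
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, chrom_sizes: Mapping[str, int]) -> "CoverageTrack":
        arrays = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "depth"])
        for row in df.itertuples(index=False):
            arrays[row.chrom][row.start : row.end] = row.depth
        return cls(arrays)


def pool_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Mean depth across samples (replicate pooling for one condition)."""
    if not tracks:
        raise ValueError("no tracks to pool")
    chroms = tracks[0].arrays.keys()
    return CoverageTrack(
        {c: np.mean([t.arrays[c] for t in tracks], axis=0) for c in chroms}
    )


# ---------------------------------------------------------------------------
# Gene counts and expression summaries
# ---------------------------------------------------------------------------

def write_gene_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def compute_fpkm(
    counts: pd.DataFrame,
    models: Sequence[GeneModel],
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """FPKM = count * 1e9 / (library_size * exonic_length).

    ``counts`` is genes x samples; library sizes default to the per-sample
    column sums. Exonic length is that of the gene's longest transcript.
    """
    lengths = pd.Series({g.gene_id: g.exonic_length for g in models}, name="length")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"genes absent from annotation: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("zero-length gene")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("library size must be positive")
    return counts * 1e9 / np.outer(lengths.values, library_sizes.values)


def log2_fold_change(
    fpkm: pd.DataFrame,
    treated: Sequence[str],
    control: Sequence[str],
    pseudocount: float = LOG2FC_PSEUDOCOUNT,
) -> pd.Series:
    """log2((mean FPKM_treated + eps) / (mean FPKM_control + eps))."""
    t = fpkm[list(treated)].mean(axis=1)
    c = fpkm[list(control)].mean(axis=1)
    return np.log2((t + pseudocount) / (c + pseudocount)).rename("log2fc")
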