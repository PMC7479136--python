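"""Genomic-region labelling of binding peaks.

Each peak receives exactly one label by precedence::

    exon-intron boundary > CDS > 5UTR > 3UTR > intron > antisense > intergenic

The boundary label fires when a peak covers both the last exonic and the
first intronic base of a splice junction on a same-strand gene — the peak
class bridging exon and intron. Within a gene, the longest transcript is
authoritative for the CDS/UTR/intron split.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel

BOUNDARY = "exon-intron boundary"
CDS = "CDS"
UTR5 = "5UTR"
UTR3 = "3UTR"
INTRON = "intron"
ANTISENSE = "antisense"
INTERGENIC = "intergenic"

#: region labels from highest to lowest precedence
REGION_PRECEDENCE = [BOUNDARY, CDS, UTR5, UTR3, INTRON, ANTISENSE, INTERGENIC]
_RANK = {label: i for i, label in enumerate(REGION_PRECEDENCE)}


class RegionAnnotator:
    """Assigns one region label per interval against a fixed gene set."""

    def __init__(self, models: Sequence[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        for g in models:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree[g.span.start : g.span.end] = g

    def annotate(self, chrom: str, start: int, end: int, strand: str) -> str:
        if start >= end:
            raise ValueError("empty peak interval")
        labels = [INTERGENIC]
        tree = self._trees.get(chrom)
        hits = tree[start:end] if tree is not None else ()
        for hit in hits:
            gene: GeneModel = hit.data
            if gene.strand != strand:
                labels.append(ANTISENSE)
                continue
            labels.extend(self._sense_labels(gene, start, end))
        return min(labels, key=_RANK.__getitem__)

    @staticmethod
    def _sense_labels(gene: GeneModel, start: int, end: int) -> list[str]:
        t = gene.primary_transcript
        labels: list[str] = []
        # exon-intron boundaries: interior exon edges of the transcript
        for left, right in t.junctions():
            for b in (left, right):
                if start < b < end:
                    labels.append(BOUNDARY)
        parts = t.utr_cds_partition(gene.strand)
        for label, key in ((CDS, "CDS"), (UTR5, "5UTR"), (UTR3, "3UTR")):
            if any(iv.start < end and start < iv.end for iv in parts[key]):
                labels.append(label)
        for iv in t.introns:
            if iv.start < end and start < iv.end:
                labels.append(INTRON)
        return labels

    def annotate_peaks(self, peaks: pd.DataFrame) -> pd.DataFrame:
        """Add a ``region`` column to a BED-like peak table."""
        out = peaks.copy()
        out["region"] = [
            self.annotate(r.chrom, r.start, r.end, r.strand)
            for r in peaks.itertuples(index=False)
        ]
        return out


def annotate_peak_region(
    models: Sequence[GeneModel], chrom: str, start: int, end: int, strand: str
) -> str:
    """One-shot convenience wrapper around :class:`RegionAnnotator`."""
    return RegionAnnotator(models).annotate(chrom, start, end, strand)
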