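"""Gene/transcript/exon coordinate hierarchy.

All coordinates are 0-based half-open on the genomic forward strand.
Strand only affects the *interpretation* of coordinates (TSS side,
donor/acceptor roles, UTR polarity), never their storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class Transcript:
    """One isoform: sorted, non-overlapping exons plus an optional CDS span.

    ``cds`` is the genomic span [cds_start, cds_end) of the coding region;
    the 5'/3' UTR split is derived from it together with the strand.
    """

    transcript_id: str
    exons: list[Interval]
    cds: Optional[Interval] = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def introns(self) -> list[Interval]:
        return [
            Interval(a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def junctions(self) -> list[tuple[int, int]]:
        """Annotated splice junctions as (left_exon_end, right_exon_start)."""
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]

    def utr_cds_partition(self, strand: str) -> dict[str, list[Interval]]:
        """Partition exonic bases into 5'UTR / CDS / 3'UTR intervals."""
        if self.cds is None:
            return {"5UTR": [], "CDS": [], "3UTR": list(self.exons)}
        left, right, cds = [], [], []
        for e in self.exons:
            if e.end <= self.cds.start:
                left.append(e)
            elif e.start >= self.cds.end:
                right.append(e)
            else:
                if e.start < self.cds.start:
                    left.append(Interval(e.start, self.cds.start))
                if e.end > self.cds.end:
                    right.append(Interval(self.cds.end, e.end))
                cds.append(
                    Interval(max(e.start, self.cds.start), min(e.end, self.cds.end))
                )
        if strand == "+":
            return {"5UTR": left, "CDS": cds, "3UTR": right}
        return {"5UTR": right, "CDS": cds, "3UTR": left}


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")

    @property
    def span(self) -> Interval:
        return Interval(
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
        )

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost coordinate on '+', rightmost on '-'."""
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def primary_transcript(self) -> Transcript:
        """Longest transcript (by exonic length); authoritative for region labels."""
        return max(self.transcripts, key=lambda t: (t.exonic_length, t.transcript_id))

    @property
    def exonic_length(self) -> int:
        return self.primary_transcript.exonic_length

    def internal_exons(self, transcript: Optional[Transcript] = None) -> list[Interval]:
        """Exons flanked by an intron on both sides."""
        t = transcript or self.primary_transcript
        return [e for e in t.exons[1:-1]]


def genes_by_chrom(models: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in models:
        out.setdefault(g.chrom, []).append(g)
    for gs in out.values():
        gs.sort(key=lambda g: g.span.start)
    return out


def iter_junction_genes(models: Sequence[GeneModel]) -> Iterator[GeneModel]:
    for g in models:
        if len(g.primary_transcript.exons) > 1:
            yield g
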