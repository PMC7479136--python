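"""Alternative-splicing event detection and differential-splicing statistics.

Junction-based events are classified purely from splice-junction topology
against the annotated (primary) transcript of each gene:

* ``ES`` — one junction skipping exactly one annotated exon;
* ``CassetteExon`` — one junction skipping a run of >= 2 consecutive exons;
* ``MXE`` — two junctions skipping adjacent exons whose connecting annotated
  junction carries (essentially) no reads: the two exons are mutually
  exclusive;
* ``5pMXE`` / ``3pMXE`` — the mutually exclusive pair sits at the transcript
  5'/3' end (alternative first/last exons);
* ``A5SS`` / ``A3SS`` — a junction sharing one annotated end while the other
  end is novel; donor-side vs acceptor-side is resolved by strand.

Intron retention is called from per-base coverage with two criteria:
boundary evidence at a splice site of the candidate intron, and a mean
intron depth of at least 20% of the flanking-exon depth and twice the
gene's background intronic depth. The intron/flank mean-depth ratio is the
IR intensity.

Differential splicing per event uses a two-sided Fisher's exact test on the
pooled 2x2 table of alternative vs model-form reads in the two conditions,
with effect size (the RASE ratio) defined as the absolute difference of the
alternative-read proportions. An event is significant when p < 0.05 and
RASE ratio > 0.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exact import fisher_exact_two_sided
from .io import CoverageTrack
from .models import GeneModel, Interval

CASSETTE = "CassetteExon"
ES = "ES"
MXE = "MXE"
A5SS = "A5SS"
A3SS = "A3SS"
MXE5P = "5pMXE"
MXE3P = "3pMXE"
INTRON_R = "IntronR"

EVENT_TYPES = (CASSETTE, ES, MXE, A5SS, A3SS, MXE5P, MXE3P, INTRON_R)

P_THRESHOLD = 0.05
RATIO_THRESHOLD = 0.2

Junction = tuple[int, int]  # (left exon end, right exon start), genomic


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    etype: str
    chrom: str
    strand: str
    model_junctions: tuple[Junction, ...]
    alt_junctions: tuple[Junction, ...]
    span: tuple[int, int]
    intron: Optional[Interval] = None  # IntronR only

    def __post_init__(self) -> None:
        if set(self.model_junctions) & set(self.alt_junctions):
            raise ValueError(f"{self.event_id}: model/alt junction sets overlap")


@dataclass
class DetectionResult:
    events: list[ASEvent]
    unclassified: pd.DataFrame  # junctions in a gene but with no topology label
    orphans: pd.DataFrame  # junctions with no host gene


@dataclass
class RASEResult:
    event: ASEvent
    alt_a: int
    model_a: int
    alt_b: int
    model_b: int
    p_value: float
    rase_ratio: float
    significant: bool
    degenerate: bool = False
    ir_intensity_a: Optional[float] = None
    ir_intensity_b: Optional[float] = None


# ---------------------------------------------------------------------------
# Junction-based event detection
# ---------------------------------------------------------------------------

def pool_junction_counts(junctions: pd.DataFrame) -> pd.DataFrame:
    """Sum junction counts over samples."""
    return (
        junctions.groupby(["chrom", "donor_end", "acceptor_start", "strand"], as_index=False)[
            "count"
        ].sum()
    )


def detect_junction_events(
    models: Sequence[GeneModel],
    junctions: pd.DataFrame,
    min_alt_count: int = 1,
    mxe_co_occurrence_frac: float = 0.05,
) -> DetectionResult:
    """Classify observed junctions inconsistent with the annotated isoform.

    ``mxe_co_occurrence_frac``: the annotated junction connecting two
    candidate mutually exclusive exons must carry at most this fraction of
    the exclusive-path read support for the pair to be called MXE (rather
    than two independent skipping events).
    """
    pooled = pool_junction_counts(junctions)
    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for r in pooled.itertuples(index=False):
        by_key.setdefault((r.chrom, r.strand), []).append(
            (int(r.donor_end), int(r.acceptor_start), int(r.count))
        )

    events: list[ASEvent] = []
    unclassified_rows = []
    claimed: set[tuple[str, str, int, int]] = set()
    for gene in sorted(models, key=lambda g: (g.chrom, g.span.start)):
        t = gene.primary_transcript
        exons = t.exons
        if len(exons) < 2:
            continue
        end2idx = {e.end: i for i, e in enumerate(exons)}
        start2idx = {e.start: i for i, e in enumerate(exons)}
        ann = {j: 0 for j in t.junctions()}
        alts: dict[Junction, int] = {}
        for l, r, cnt in by_key.get((gene.chrom, gene.strand), []):
            if not (gene.span.start <= l and r <= gene.span.end):
                continue
            claimed.add((gene.chrom, gene.strand, l, r))
            if (l, r) in ann:
                ann[(l, r)] += cnt
            elif cnt >= min_alt_count:
                alts[(l, r)] = alts.get((l, r), 0) + cnt

        skips: dict[tuple[int, int], tuple[Junction, int]] = {}
        side_events: list[tuple[str, Junction, Junction]] = []
        for (l, r), cnt in sorted(alts.items()):
            i = end2idx.get(l)
            j = start2idx.get(r)
            if i is not None and j is not None and j >= i + 2:
                skips[(i, j)] = ((l, r), cnt)
            elif i is not None and i + 1 < len(exons) and l < r < exons[i + 1].end:
                # novel right end of the intron after exon i
                etype = A3SS if gene.strand == "+" else A5SS
                side_events.append((etype, (exons[i].end, exons[i + 1].start), (l, r)))
            elif j is not None and j >= 1 and exons[j - 1].start < l < r:
                etype = A5SS if gene.strand == "+" else A3SS
                side_events.append((etype, (exons[j - 1].end, exons[j].start), (l, r)))
            else:
                unclassified_rows.append(
                    dict(gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                         donor_end=l, acceptor_start=r, count=cnt)
                )

        events.extend(
            _classify_skips(gene, exons, ann, skips, mxe_co_occurrence_frac)
        )
        for etype, mj, aj in side_events:
            events.append(_make_event(gene, etype, (mj,), (aj,)))

    orphan_rows = [
        dict(chrom=c, strand=s, donor_end=l, acceptor_start=r, count=cnt)
        for (c, s), recs in by_key.items()
        for (l, r, cnt) in recs
        if (c, s, l, r) not in claimed
    ]
    cols_u = ["gene_id", "chrom", "strand", "donor_end", "acceptor_start", "count"]
    cols_o = ["chrom", "strand", "donor_end", "acceptor_start", "count"]
    return DetectionResult(
        events=events,
        unclassified=pd.DataFrame(unclassified_rows, columns=cols_u),
        orphans=pd.DataFrame(orphan_rows, columns=cols_o),
    )


def _classify_skips(gene, exons, ann, skips, co_frac):
    """Resolve exon-skipping junctions into MXE/5pMXE/3pMXE/ES/CassetteExon.

    Precedence: MXE > terminal MXE (5p/3p) > CassetteExon/ES.
    """
    events = []
    used: set[tuple[int, int]] = set()
    n = len(exons)

    def junction(i: int, j: int) -> Junction:
        return (exons[i].end, exons[j].start)

    # mutually exclusive internal exon pairs: skips (i, i+2) and (i+1, i+3)
    for (i, j) in sorted(skips):
        if j != i + 2 or (i, j) in used:
            continue
        partner = (i + 1, i + 3)
        if partner in skips and partner not in used and i + 3 <= n - 1:
            connect = ann.get(junction(i + 1, i + 2), 0)
            support = skips[(i, j)][1] + skips[partner][1]
            if connect <= co_frac * support:
                used.update({(i, j), partner})
                model = (junction(i, i + 1), skips[partner][0])
                alt = (skips[(i, j)][0], junction(i + 2, i + 3))
                events.append(_make_event(gene, MXE, model, alt))

    # alternative first/last exons
    for (i, j) in sorted(skips):
        if (i, j) in used or j != i + 2:
            continue
        skip_j, cnt = skips[(i, j)]
        if i == 0 and n >= 3:
            connect = ann.get(junction(0, 1), 0)
            if connect <= co_frac * cnt:
                used.add((i, j))
                etype = MXE5P if gene.strand == "+" else MXE3P
                events.append(_make_event(gene, etype, (junction(1, 2),), (skip_j,)))
                continue
        if j == n - 1 and n >= 3:
            connect = ann.get(junction(n - 2, n - 1), 0)
            if connect <= co_frac * cnt:
                used.add((i, j))
                etype = MXE3P if gene.strand == "+" else MXE5P
                events.append(_make_event(gene, etype, (junction(n - 3, n - 2),), (skip_j,)))

    # plain skipping
    for (i, j) in sorted(skips):
        if (i, j) in used:
            continue
        skip_j, _ = skips[(i, j)]
        etype = ES if j - i - 1 == 1 else CASSETTE
        model = (junction(i, i + 1), junction(j - 1, j))
        events.append(_make_event(gene, etype, model, (skip_j,)))
    return events


def _make_event(gene: GeneModel, etype: str, model, alt) -> ASEvent:
    coords = [c for j in (*model, *alt) for c in j]
    span = (min(coords), max(coords))
    event_id = f"{gene.gene_id}:{etype}:{span[0]}-{span[1]}"
    return ASEvent(
        event_id=event_id,
        gene_id=gene.gene_id,
        etype=etype,
        chrom=gene.chrom,
        strand=gene.strand,
        model_junctions=tuple(model),
        alt_junctions=tuple(alt),
        span=span,
    )


# ---------------------------------------------------------------------------
# Intron retention
# ---------------------------------------------------------------------------

def compute_ir_intensity(intron_depth: np.ndarray, flank_depth: np.ndarray) -> float:
    """Mean intron depth over mean flanking-exon depth; NaN when the flank
    has no coverage (undefined)."""
    flank_mean = float(np.mean(flank_depth)) if len(flank_depth) else 0.0
    if flank_mean <= 0:
        return math.nan
    return float(np.mean(intron_depth)) / flank_mean


def call_intron_retention(
    models: Sequence[GeneModel],
    coverage: CoverageTrack,
    min_boundary_depth: float = 1.0,
    flank_fraction: float = 0.2,
    baseline_multiple: float = 2.0,
) -> list[ASEvent]:
    """Call retained introns from one condition's pooled coverage.

    An intron is reported when (1) depth at its first or last intronic base
    reaches ``min_boundary_depth`` (boundary evidence) and (2) its mean depth
    is >= ``flank_fraction`` x the mean flanking-exon depth AND >=
    ``baseline_multiple`` x the gene's background intronic depth (median of
    the gene's other introns; vacuous for single-intron genes).
    """
    events: list[ASEvent] = []
    for gene in sorted(models, key=lambda g: (g.chrom, g.span.start)):
        t = gene.primary_transcript
        introns = t.introns
        if not introns:
            continue
        intron_means = [coverage.mean(gene.chrom, iv.start, iv.end) for iv in introns]
        for k, iv in enumerate(introns):
            left_exon, right_exon = t.exons[k], t.exons[k + 1]
            flank = np.concatenate(
                [
                    coverage.depth(gene.chrom, left_exon.start, left_exon.end),
                    coverage.depth(gene.chrom, right_exon.start, right_exon.end),
                ]
            )
            flank_mean = float(flank.mean())
            m = intron_means[k]
            arr = coverage.arrays[gene.chrom]
            boundary = (
                arr[iv.start] >= min_boundary_depth
                or arr[iv.end - 1] >= min_boundary_depth
            )
            others = [x for i, x in enumerate(intron_means) if i != k]
            baseline = median(others) if others else 0.0
            if (
                boundary
                and flank_mean > 0
                and m >= flank_fraction * flank_mean
                and m >= baseline_multiple * baseline
            ):
                ev = ASEvent(
                    event_id=f"{gene.gene_id}:{INTRON_R}:{iv.start}-{iv.end}",
                    gene_id=gene.gene_id,
                    etype=INTRON_R,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    model_junctions=((iv.start, iv.end),),
                    alt_junctions=(),
                    span=(left_exon.start, right_exon.end),
                    intron=iv,
                )
                events.append(ev)
    return events


# ---------------------------------------------------------------------------
# Differential statistics
# ---------------------------------------------------------------------------

def rase_test(
    alt_a: int,
    model_a: int,
    alt_b: int,
    model_b: int,
    p_threshold: float = P_THRESHOLD,
    ratio_threshold: float = RATIO_THRESHOLD,
) -> tuple[float, float, bool, bool]:
    """Fisher p and RASE ratio for one event's pooled 2x2 table.

    Returns (p_value, rase_ratio, significant, degenerate). The RASE ratio is
    |alt_a/(alt_a+model_a) - alt_b/(alt_b+model_b)|; a table with an all-zero
    condition is degenerate (p = 1, ratio 0).
    """
    tot_a, tot_b = alt_a + model_a, alt_b + model_b
    if tot_a == 0 or tot_b == 0:
        return 1.0, 0.0, False, True
    p = fisher_exact_two_sided(alt_a, model_a, alt_b, model_b)
    ratio = abs(alt_a / tot_a - alt_b / tot_b)
    return p, ratio, (p < p_threshold and ratio > ratio_threshold), False


def _junction_count_index(
    junctions: pd.DataFrame, samples: Mapping[str, Sequence[str]]
) -> dict[str, dict[tuple, int]]:
    """condition -> {(chrom, strand, left, right): pooled count}."""
    sample_to_cond = {s: c for c, ss in samples.items() for s in ss}
    index: dict[str, dict[tuple, int]] = {c: {} for c in samples}
    for r in junctions.itertuples(index=False):
        cond = sample_to_cond.get(r.sample)
        if cond is None:
            continue
        key = (r.chrom, r.strand, int(r.donor_end), int(r.acceptor_start))
        d = index[cond]
        d[key] = d.get(key, 0) + int(r.count)
    return index


def event_condition_counts(
    event: ASEvent,
    junctions: pd.DataFrame,
    samples: Mapping[str, Sequence[str]],
    coverage: Optional[Mapping[str, CoverageTrack]] = None,
    read_length: int = 100,
    _index: Optional[dict[str, dict[tuple, int]]] = None,
) -> dict[str, tuple[int, int, Optional[float]]]:
    """(alt, model, ir_intensity) reads per condition, replicates pooled.

    For junction events both counts come from the junction table. For
    IntronR the model reads are the spliced-junction reads of the candidate
    intron and the alternative reads are intron-body read equivalents
    (mean intron depth x intron length / read length), with IR intensity
    computed against the flanking exons.
    """
    out = {}
    index = _index if _index is not None else _junction_count_index(junctions, samples)
    for cond in samples:
        counts = index[cond]

        def get(j: Junction) -> int:
            return counts.get((event.chrom, event.strand, j[0], j[1]), 0)

        model = sum(get(j) for j in event.model_junctions)
        if event.etype == INTRON_R:
            if coverage is None or cond not in coverage:
                raise ValueError("IntronR counting requires per-condition coverage")
            cov = coverage[cond]
            iv = event.intron
            intron_depth = cov.depth(event.chrom, iv.start, iv.end)
            alt = int(round(float(intron_depth.mean()) * len(iv) / read_length))
            gene_exons = _flank_exons(event)
            flank = np.concatenate(
                [cov.depth(event.chrom, s, e) for s, e in gene_exons]
            )
            ir = compute_ir_intensity(intron_depth, flank)
            out[cond] = (alt, model, ir)
        else:
            alt = sum(get(j) for j in event.alt_junctions)
            out[cond] = (alt, model, None)
    return out


def _flank_exons(event: ASEvent) -> list[tuple[int, int]]:
    iv = event.intron
    return [(event.span[0], iv.start), (iv.end, event.span[1])]


def differential_splicing(
    events: Sequence[ASEvent],
    junctions: pd.DataFrame,
    samples: Mapping[str, Sequence[str]],
    coverage: Optional[Mapping[str, CoverageTrack]] = None,
    condition_a: str = "control",
    condition_b: str = "treated",
    read_length: int = 100,
    p_threshold: float = P_THRESHOLD,
    ratio_threshold: float = RATIO_THRESHOLD,
    significance: str = "pvalue",
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-event differential table; significance mode 'pvalue' (raw p) or
    'fdr' (Benjamini-Hochberg q-value against ``fdr_threshold``)."""
    rows = []
    index = _junction_count_index(junctions, samples)
    for ev in events:
        cc = event_condition_counts(
            ev, junctions, samples, coverage, read_length, _index=index
        )
        alt_a, model_a, ir_a = cc[condition_a]
        alt_b, model_b, ir_b = cc[condition_b]
        p, ratio, sig, degen = rase_test(
            alt_a, model_a, alt_b, model_b, p_threshold, ratio_threshold
        )
        rows.append(
            dict(
                event_id=ev.event_id,
                gene_id=ev.gene_id,
                type=ev.etype,
                chrom=ev.chrom,
                strand=ev.strand,
                span_start=ev.span[0],
                span_end=ev.span[1],
                alt_control=alt_a,
                model_control=model_a,
                alt_treated=alt_b,
                model_treated=model_b,
                p_value=p,
                rase_ratio=ratio,
                ir_intensity_control=ir_a,
                ir_intensity_treated=ir_b,
                significant=sig,
                degenerate=degen,
            )
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    if significance == "fdr":
        df["significant"] = (df["q_value"] < fdr_threshold) & (
            df["rase_ratio"] > ratio_threshold
        ) & ~df["degenerate"]
    return df.sort_values("event_id", ignore_index=True)
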