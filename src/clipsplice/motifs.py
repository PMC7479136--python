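"""Splicing-motif scanning, regional frequencies, binding-vs-motif binning,
and exon-intron boundary metagene profiles.

Patterns use a fuzznuc-style alphabet: plain bases, ``N`` for any base, and
``[...]`` character classes; RNA patterns (U) are matched as DNA (T).
Overlapping matches are counted. Built-in patterns cover the 5' splice-site
consensus (AGGUAAG and its degenerate form), the 3' splice-site consensus,
the GAAGAA exonic splicing enhancer, and the UGGAC m6A context; the U-rich
element upstream of 3' splice sites is operationalized as a run of >= 5 T
within a 6-nt window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CoverageTrack
from .models import GeneModel

FIVE_SS_CONSENSUS = "AGGUAAG"
FIVE_SS_DEGENERATE = "[GA]GT[AG]AG"
THREE_SS = "T[TCG][TCG]N[TC]TN[TC]AG"
ESE_GAAGAA = "GAAGAA"
M6A_UGGAC = "UGGAC"

BUILTIN_PATTERNS = {
    "5ss_AGGUAAG": FIVE_SS_CONSENSUS,
    "5ss_degenerate": FIVE_SS_DEGENERATE,
    "3ss": THREE_SS,
    "ESE_GAAGAA": ESE_GAAGAA,
    "m6A_UGGAC": M6A_UGGAC,
}

N_MOTIF_BINS = 11  # bins 0..10, top bin open-ended

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def parse_pattern(pattern: str) -> list[frozenset[str]]:
    """Expand a pattern into per-position allowed-base sets (U treated as T)."""
    if not pattern:
        raise ValueError("empty pattern")
    pattern = pattern.upper().replace("U", "T")
    out: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            out.append(frozenset(pattern[i + 1 : j]))
            i = j + 1
        elif ch == "N":
            out.append(frozenset("ACGT"))
            i += 1
        else:
            out.append(frozenset(ch))
            i += 1
    return out


def scan_motif(sequence: str, pattern: str, strand: str = "+") -> list[int]:
    """All (overlapping) match start positions of ``pattern`` in ``sequence``.

    ``strand='-'`` scans the reverse complement; returned positions are in
    reverse-complement (5'->3' on the minus strand) coordinates.
    """
    positions = parse_pattern(pattern)
    seq = sequence.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    regex = "(?=" + "".join(
        "[" + "".join(sorted(p)) + "]" if len(p) > 1 else next(iter(p))
        for p in positions
    ) + ")"
    return [m.start() for m in re.finditer(regex, seq)]


def scan_u_rich(
    sequence: str, strand: str = "+", min_t: int = 5, window: int = 6
) -> list[int]:
    """Window starts where >= ``min_t`` of ``window`` bases are T (U-rich)."""
    seq = sequence.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    is_t = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("T")
    if is_t.size < window:
        return []
    runsum = np.convolve(is_t.astype(int), np.ones(window, dtype=int), mode="valid")
    return np.flatnonzero(runsum >= min_t).tolist()


# ---------------------------------------------------------------------------
# Regional motif frequencies
# ---------------------------------------------------------------------------

def region_motif_frequency(
    peaks: pd.DataFrame,
    genome: Mapping[str, str],
    patterns: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Fraction of each region's peaks containing >= 1 motif hit.

    ``peaks`` must carry a ``region`` column (see
    :class:`~clipsplice.regions.RegionAnnotator`). Peak sequence is read on
    the peak's own strand, so antisense-labelled peaks are scanned as the
    reverse complement of the genomic interval. Regions without peaks get a
    missing proportion.
    """
    if "region" not in peaks.columns:
        raise ValueError("peaks must be region-annotated first")
    patterns = dict(patterns or BUILTIN_PATTERNS)
    rows = []
    for pat_name, pat in patterns.items():
        hit = []
        for r in peaks.itertuples(index=False):
            seq = genome[r.chrom][r.start : r.end]
            hit.append(bool(scan_motif(seq, pat, strand=r.strand)))
        df = peaks.assign(hit=hit)
        grouped = df.groupby("region")["hit"].agg(n_peaks="size", n_with_hit="sum")
        grouped["proportion"] = grouped["n_with_hit"] / grouped["n_peaks"]
        for region, row in grouped.iterrows():
            rows.append(
                dict(
                    pattern=pat_name,
                    region=region,
                    n_peaks=int(row["n_peaks"]),
                    n_with_hit=int(row["n_with_hit"]),
                    proportion=float(row["proportion"]),
                )
            )
    return pd.DataFrame(rows, columns=["pattern", "region", "n_peaks", "n_with_hit", "proportion"])


def transcript_motif_counts(
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    patterns: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Motif occurrences per gene over the oriented pre-mRNA (gene span).

    Includes a ``total`` column pooling all patterns, since binding-signal
    binning can be done per pattern class or over the pooled count.
    """
    patterns = dict(patterns or BUILTIN_PATTERNS)
    rows = {}
    for g in models:
        seq = genome[g.chrom][g.span.start : g.span.end]
        counts = {
            name: len(scan_motif(seq, pat, strand=g.strand))
            for name, pat in patterns.items()
        }
        counts["total"] = sum(counts.values())
        rows[g.gene_id] = counts
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# 11-bin motif-count vs binding-signal analysis
# ---------------------------------------------------------------------------

def bin_by_motif_count(
    motif_counts: pd.Series, binding_signal: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Median binding signal with IQR across motif-count bins 0..10.

    Counts >= 10 collapse into the open-ended top bin. Returns the per-bin
    summary (n, median, q1, q3; empty bins keep n=0 with no summary) and the
    Spearman rho between bin index and per-bin median over occupied bins.
    """
    common = motif_counts.index.intersection(binding_signal.index)
    counts = motif_counts.loc[common].astype(int)
    signal = binding_signal.loc[common].astype(float)
    bins = counts.clip(upper=N_MOTIF_BINS - 1)
    rows = []
    for b in range(N_MOTIF_BINS):
        vals = signal[bins == b]
        if len(vals):
            rows.append(
                dict(bin=b, n=len(vals), median=float(vals.median()),
                     q1=float(vals.quantile(0.25)), q3=float(vals.quantile(0.75)))
            )
        else:
            rows.append(dict(bin=b, n=0, median=np.nan, q1=np.nan, q3=np.nan))
    summary = pd.DataFrame(rows)
    occupied = summary[summary["n"] > 0]
    if len(occupied) >= 2 and occupied["median"].nunique() > 1:
        rho = float(stats.spearmanr(occupied["bin"], occupied["median"]).statistic)
    else:
        rho = float("nan")
    return summary, rho


# ---------------------------------------------------------------------------
# Metagene boundary profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Read-density profiles around internal-exon boundaries.

    The axis covers, in transcript orientation: 400 nt of upstream intron,
    the first 100 nt of the exon (3'ss anchor between them), the last 100 nt
    of the exon, and 400 nt of downstream intron (5'ss anchor between
    those). Profiles are per-group accumulated depth divided by the group's
    gene count, then jointly normalized by the global maximum (which is
    exactly 1 afterwards).
    """

    profiles: dict[str, np.ndarray]
    n_genes: dict[str, int]
    exon_flank: int
    intron_flank: int

    @property
    def anchor_3ss(self) -> int:
        return self.intron_flank

    @property
    def anchor_5ss(self) -> int:
        return self.intron_flank + 2 * self.exon_flank

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.profiles)
        df.index.name = "position"
        return df


def metagene_boundary_profile(
    tracks: Mapping[str, CoverageTrack],
    models: Sequence[GeneModel],
    peak_genes: set[str],
    exon_flank: int = 100,
    intron_flank: int = 400,
) -> MetageneProfile:
    """Boundary metagene over {peak-containing, peak-lacking} x tracks.

    Only internal exons (flanked by introns on both sides) contribute; genes
    without one are excluded. Exons/introns shorter than the flank lengths
    contribute their available positions without padding.
    """
    width = 2 * (exon_flank + intron_flank)
    keys = [f"{name}|{grp}" for name in tracks for grp in ("peak", "nonpeak")]
    sums = {k: np.zeros(width) for k in keys}
    n_genes = {k: 0 for k in keys}
    e_anchor = intron_flank  # start of exon head block
    tail_end = intron_flank + 2 * exon_flank  # end of exon tail block

    for gene in models:
        t = gene.primary_transcript
        exons, introns = t.exons, t.introns
        if len(exons) < 3:
            continue
        grp = "peak" if gene.gene_id in peak_genes else "nonpeak"
        for name, cov in tracks.items():
            key = f"{name}|{grp}"
            n_genes[key] += 1
            arr = cov.arrays[gene.chrom]
            for k in range(1, len(exons) - 1):
                if gene.strand == "+":
                    up = arr[introns[k - 1].start : introns[k - 1].end]
                    ex = arr[exons[k].start : exons[k].end]
                    dn = arr[introns[k].start : introns[k].end]
                else:
                    up = arr[introns[k].start : introns[k].end][::-1]
                    ex = arr[exons[k].start : exons[k].end][::-1]
                    dn = arr[introns[k - 1].start : introns[k - 1].end][::-1]
                m = min(intron_flank, up.size)
                sums[key][e_anchor - m : e_anchor] += up[up.size - m :]
                m = min(exon_flank, ex.size)
                sums[key][e_anchor : e_anchor + m] += ex[:m]
                sums[key][tail_end - m : tail_end] += ex[ex.size - m :]
                m = min(intron_flank, dn.size)
                sums[key][tail_end : tail_end + m] += dn[:m]

    profiles = {
        k: (sums[k] / n_genes[k] if n_genes[k] else sums[k]) for k in keys
    }
    global_max = max(p.max() for p in profiles.values())
    if global_max <= 0:
        raise ValueError("no coverage in any metagene group")
    profiles = {k: p / global_max for k, p in profiles.items()}
    return MetageneProfile(profiles, n_genes, exon_flank, intron_flank)
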