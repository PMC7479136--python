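"""Binding-affinity scoring, tier stratification, and ECDF shift analysis.

CLIP affinity per gene is the peak-derived binding signal normalized by the
gene's control expression (FPKM); ChIP promoter affinity is the sum of peak
fold enrichments inside the promoter window (default 10 kb upstream to 3 kb
downstream of the TSS). Bound genes are stratified into strong / median /
weak tiers by affinity tertiles, and per-tier response distributions
(e.g. knockout/control log2 fold changes) are compared by one-way ANOVA
with Tukey's pairwise test, with a strong-vs-weak Kolmogorov-Smirnov
statistic reported alongside the ECDF curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exact import hypergeom_upper_tail
from .models import GeneModel

STRONG, MEDIAN, WEAK, UNBOUND = "strong", "median", "weak", "unbound"
TIER_ORDER = [STRONG, MEDIAN, WEAK]

PROMOTER_UPSTREAM = 10_000
PROMOTER_DOWNSTREAM = 3_000
#: alternate preset matching the ENCODE-comparison window
PROMOTER_ENCODE = (5_000, 2_000)


def clip_signal_from_peaks(
    peaks: pd.DataFrame, models: Sequence[GeneModel]
) -> pd.Series:
    """Per-gene CLIP binding signal from a peak table.

    Peak read counts are not part of the BED input, so the signal is the sum
    of fold_enrichment x peak length over peaks overlapping the gene span on
    the sense strand.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in models:
        trees.setdefault((g.chrom, g.strand), IntervalTree())[
            g.span.start : g.span.end
        ] = g.gene_id
    signal = {g.gene_id: 0.0 for g in models}
    for r in peaks.itertuples(index=False):
        tree = trees.get((r.chrom, r.strand))
        if tree is None:
            continue
        for hit in tree[r.start : r.end]:
            signal[hit.data] += r.fold_enrichment * (r.end - r.start)
    return pd.Series(signal, name="clip_signal").sort_index()


def score_clip_affinity(
    clip_signal: pd.Series, control_fpkm: pd.Series
) -> pd.DataFrame:
    """Affinity = clip_signal / control FPKM.

    Genes with zero or missing control FPKM cannot be normalized; they are
    excluded with a warning. Genes without signal get affinity 0 and tier
    'unbound'.
    """
    df = pd.DataFrame({"clip_signal": clip_signal})
    df["control_fpkm"] = control_fpkm.reindex(df.index)
    bad = df.index[(df["control_fpkm"].isna()) | (df["control_fpkm"] <= 0)]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} gene(s) with zero/missing control FPKM "
            f"(e.g. {list(bad[:3])})"
        )
        df = df.drop(index=bad)
    df["clip_affinity"] = df["clip_signal"] / df["control_fpkm"]
    df["clip_tier"] = UNBOUND
    return df


def tier_genes(
    records: pd.DataFrame,
    mode: str = "clip",
    quantiles: tuple[float, float] = (1 / 3, 2 / 3),
) -> pd.DataFrame:
    """Split bound genes into weak/median/strong by affinity tertiles.

    ``mode`` selects the affinity column ('clip' -> clip_affinity,
    'chip' -> chip_promoter_score). Unbound genes (affinity 0) keep the
    'unbound' tier. Degenerate all-equal affinities collapse to a single
    'median' tier with a warning.
    """
    col = {"clip": "clip_affinity", "chip": "chip_promoter_score"}[mode]
    tier_col = {"clip": "clip_tier", "chip": "chip_tier"}[mode]
    out = records.copy()
    bound = out.index[out[col] > 0]
    if len(bound) < 3:
        raise ValueError(f"need >= 3 bound genes to stratify, got {len(bound)}")
    vals = out.loc[bound, col].to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        warnings.warn("all affinities equal; assigning a single 'median' tier")
        out.loc[bound, tier_col] = MEDIAN
        return out
    q1, q2 = np.quantile(vals, quantiles)
    tiers = np.where(vals <= q1, WEAK, np.where(vals <= q2, MEDIAN, STRONG))
    out[tier_col] = out.get(tier_col, UNBOUND)
    out.loc[bound, tier_col] = tiers
    return out


@dataclass
class EcdfComparison:
    tier_values: dict[str, np.ndarray]
    ecdf: dict[str, tuple[np.ndarray, np.ndarray]]
    medians: dict[str, float]
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    ks_stat: float
    ks_p: float


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and the right-continuous ECDF heights (ends at 1)."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, x.size + 1) / x.size
    return x, y


def ecdf_shift_analysis(
    tiered: pd.DataFrame,
    response: pd.Series,
    tier_col: str = "clip_tier",
    pairwise: bool = True,
) -> EcdfComparison:
    """Compare per-tier response distributions.

    One-way ANOVA across the strong/median/weak tiers with Tukey HSD
    pairwise p-values (skipped when ``pairwise`` is False); the
    strong-vs-weak KS statistic accompanies the ECDF curves. Tiers with no
    genes are dropped with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    for tier in TIER_ORDER:
        genes = tiered.index[tiered[tier_col] == tier]
        vals = response.reindex(genes).dropna().to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"tier {tier!r} is empty; excluded from comparison")
            continue
        groups[tier] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty tiers")
    vecs = list(groups.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p = stats.f_oneway(*vecs)
    if pairwise:
        endog = np.concatenate(vecs)
        labels = np.concatenate([[t] * len(v) for t, v in groups.items()])
        tk = pairwise_tukeyhsd(endog, labels)
        tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    else:
        tukey = pd.DataFrame(columns=["group1", "group2", "meandiff", "p-adj",
                                      "lower", "upper", "reject"])
    if STRONG in groups and WEAK in groups:
        ks_stat, ks_p = stats.ks_2samp(groups[STRONG], groups[WEAK])
    else:
        ks_stat, ks_p = float("nan"), float("nan")
    return EcdfComparison(
        tier_values=groups,
        ecdf={t: ecdf(v) for t, v in groups.items()},
        medians={t: float(np.median(v)) for t, v in groups.items()},
        anova_f=float(f_stat),
        anova_p=float(p),
        tukey=tukey,
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
    )


def score_chip_promoter(
    peaks: pd.DataFrame,
    models: Sequence[GeneModel],
    window_up: int = PROMOTER_UPSTREAM,
    window_down: int = PROMOTER_DOWNSTREAM,
) -> pd.Series:
    """Sum of peak fold enrichments in each gene's promoter window.

    The window is [TSS - window_up, TSS + window_down) in the direction of
    transcription (mirrored on '-' strand genes); any >= 1 bp overlap
    counts. ChIP peaks are DNA intervals, so peak strand is ignored.
    """
    scores = {g.gene_id: 0.0 for g in models}
    windows = []
    for g in models:
        if g.strand == "+":
            windows.append((g.chrom, g.tss - window_up, g.tss + window_down, g.gene_id))
        else:
            windows.append((g.chrom, g.tss - window_down, g.tss + window_up, g.gene_id))
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, gid in windows:
        trees.setdefault(chrom, IntervalTree())[s:e] = gid
    for r in peaks.itertuples(index=False):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in tree[r.start : r.end]:
            scores[hit.data] += r.fold_enrichment
    return pd.Series(scores, name="chip_promoter_score").sort_index()


def hypergeometric_overlap(
    set_a: Iterable, set_b: Iterable, universe: Iterable
) -> float:
    """Upper-tail probability of observing >= |A & B| shared members."""
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    stray = (a | b) - u
    if stray:
        raise ValueError(f"sets exceed universe: {sorted(stray)[:5]}")
    return hypergeom_upper_tail(len(a & b), len(u), len(a), len(b))


def pearson_coexpression(
    matrix: pd.DataFrame,
    anchor: str,
    threshold: float = 0.3,
) -> pd.Series:
    """Genes whose expression correlates with the anchor at |PCC| >= threshold.

    ``matrix`` is genes x samples (>= 3 samples). Zero-variance genes have an
    undefined PCC and are excluded with a warning; the returned correlations
    are signed. The anchor itself is not reported.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation screening")
    if anchor not in matrix.index:
        raise ValueError(f"anchor gene {anchor!r} absent from matrix")
    x = matrix.loc[anchor].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("anchor gene has zero variance")
    others = matrix.drop(index=anchor)
    sds = others.std(axis=1, ddof=0)
    flat = others.index[sds == 0]
    if len(flat):
        warnings.warn(f"excluding {len(flat)} zero-variance gene(s)")
        others = others.drop(index=flat)
    xc = x - x.mean()
    yc = others.to_numpy(dtype=float) - others.mean(axis=1).to_numpy()[:, None]
    pcc = (yc @ xc) / (np.sqrt((yc**2).sum(axis=1)) * np.sqrt((xc**2).sum()))
    pcc = pd.Series(pcc, index=others.index, name="pcc")
    return pcc[pcc.abs() >= threshold].sort_values(ascending=False)
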