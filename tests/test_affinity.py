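"""Affinity scoring, tier stratification, ECDF comparison, overlap tests."""

import numpy as np
import pandas as pd
import pytest

from clipsplice.affinity import (
    clip_signal_from_peaks,
    ecdf,
    ecdf_shift_analysis,
    hypergeometric_overlap,
    pearson_coexpression,
    score_chip_promoter,
    score_clip_affinity,
    tier_genes,
)
from clipsplice.evaluate import tier_effect_trial, tier_rank_recovery, tukey_pair_p
from clipsplice.models import GeneModel, Interval, Transcript


def test_affinity_is_signal_over_control_fpkm():
    signal = pd.Series({"gA": 100.0, "gB": 0.0})
    fpkm = pd.Series({"gA": 50.0, "gB": 10.0})
    rec = score_clip_affinity(signal, fpkm)
    assert rec.loc["gA", "clip_affinity"] == pytest.approx(2.0)
    assert rec.loc["gB", "clip_affinity"] == 0.0
    assert rec.loc["gB", "clip_tier"] == "unbound"


def test_zero_fpkm_genes_excluded_with_warning():
    signal = pd.Series({"gA": 10.0, "gB": 10.0})
    fpkm = pd.Series({"gA": 5.0, "gB": 0.0})
    with pytest.warns(UserWarning, match="control FPKM"):
        rec = score_clip_affinity(signal, fpkm)
    assert list(rec.index) == ["gA"]


def test_tertile_split_three_per_tier():
    rec = pd.DataFrame({"clip_affinity": np.arange(1.0, 10.0)},
                       index=[f"g{i}" for i in range(9)])
    rec["clip_tier"] = "unbound"
    out = tier_genes(rec, "clip")
    assert (out["clip_tier"].value_counts()[["weak", "median", "strong"]] == 3).all()


def test_tier_boundaries_match_percentile_oracle():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(0, 1, 10_000)
    rec = pd.DataFrame({"clip_affinity": vals},
                       index=[f"g{i}" for i in range(vals.size)])
    out = tier_genes(rec, "clip")
    q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
    weak_max = out.loc[out["clip_tier"] == "weak", "clip_affinity"].max()
    strong_min = out.loc[out["clip_tier"] == "strong", "clip_affinity"].min()
    assert weak_max <= q1 < strong_min
    assert out.loc[out["clip_tier"] == "median", "clip_affinity"].between(q1, q2, inclusive="both").all()
    assert strong_min > q2


def test_all_equal_affinities_collapse_to_median():
    rec = pd.DataFrame({"clip_affinity": [2.0] * 5}, index=list("abcde"))
    with pytest.warns(UserWarning, match="equal"):
        out = tier_genes(rec, "clip")
    assert (out["clip_tier"] == "median").all()


def test_too_few_bound_genes_rejected():
    rec = pd.DataFrame({"clip_affinity": [1.0, 2.0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="bound"):
        tier_genes(rec, "clip")


def test_ecdf_properties():
    x, y = ecdf(np.array([3.0, 1.0, 2.0]))
    assert (np.diff(x) >= 0).all()
    assert (np.diff(y) >= 0).all()
    assert y[0] > 0 and y[-1] == 1.0


def test_identical_tiers_show_no_effect():
    vec = np.array([0.1, -0.2, 0.5, 0.3, -0.4])
    genes = [f"{t}{i}" for t in "smw" for i in range(5)]
    tiers = ["strong"] * 5 + ["median"] * 5 + ["weak"] * 5
    tiered = pd.DataFrame({"clip_tier": tiers}, index=genes)
    resp = pd.Series(np.tile(vec, 3), index=genes)
    cmp_ = ecdf_shift_analysis(tiered, resp)
    assert cmp_.anova_p >= 0.99
    assert cmp_.ks_stat == 0.0


def test_anova_f_matches_hand_computation():
    """3 groups x 5 values, F computed from the definition."""
    groups = {
        "strong": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        "median": np.array([2.0, 3.0, 4.0, 5.0, 6.0]),
        "weak": np.array([5.0, 6.0, 7.0, 8.0, 9.0]),
    }
    genes, tiers, vals = [], [], []
    for t, v in groups.items():
        for i, x in enumerate(v):
            genes.append(f"{t}{i}"); tiers.append(t); vals.append(x)
    cmp_ = ecdf_shift_analysis(
        pd.DataFrame({"clip_tier": tiers}, index=genes), pd.Series(vals, index=genes)
    )
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    f_hand = (ss_between / 2) / (ss_within / 12)
    assert cmp_.anova_f == pytest.approx(f_hand, rel=1e-12)


def test_planted_tier_destabilization_recovered():
    ordering, p_sw, ks_p = tier_effect_trial(seed=123)
    assert ordering
    assert p_sw < 0.01
    assert ks_p < 0.01


def test_affinity_rank_tracks_planted_tiers(sim_study):
    from clipsplice.io import compute_fpkm

    fpkm = compute_fpkm(sim_study.gene_counts, sim_study.models)
    ctrl = fpkm[sim_study.samples["control"]].mean(axis=1)
    signal = clip_signal_from_peaks(sim_study.binding.clip_peaks, sim_study.models)
    aff = tier_genes(score_clip_affinity(signal, ctrl), "clip")
    assert tier_rank_recovery(sim_study, aff) > 0.8


# ---------------------------------------------------------------------------
# ChIP promoter scores
# ---------------------------------------------------------------------------

def _gene(gene_id, chrom, strand, start, end):
    return GeneModel(gene_id, chrom, strand,
                     [Transcript(f"{gene_id}.t", [Interval(start, end)])])


def peak_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "fold_enrichment", "strand"])


def test_promoter_score_sums_fold_enrichment():
    gene = _gene("g1", "chr1", "+", 50_000, 60_000)  # TSS = 50_000
    peaks = peak_df([
        ("chr1", 48_000, 48_200, "p1", 3.0, "."),
        ("chr1", 51_000, 51_200, "p2", 2.5, "."),
        ("chr1", 38_000, 38_100, "p3", 9.9, "."),  # 12 kb upstream: outside
    ])
    score = score_chip_promoter(peaks, [gene])
    assert score["g1"] == pytest.approx(5.5)


def test_promoter_window_mirrored_on_minus_strand():
    gene = _gene("g1", "chr1", "-", 50_000, 60_000)  # TSS = 60_000
    peaks = peak_df([
        ("chr1", 62_000, 62_200, "p1", 4.0, "."),   # 2 kb upstream (genomic right)
        ("chr1", 58_000, 58_100, "p2", 1.5, "."),   # 2 kb downstream
        ("chr1", 56_000, 56_500, "p3", 7.0, "."),   # 4 kb downstream: outside
    ])
    score = score_chip_promoter(peaks, [gene])
    assert score["g1"] == pytest.approx(5.5)


def test_promoter_score_matches_per_base_oracle(sim_tiny):
    """Window-rule scores equal an explicit per-gene overlap loop."""
    peaks = sim_tiny.binding.chip_peaks
    scores = score_chip_promoter(peaks, sim_tiny.models)
    for gene in sim_tiny.models:
        if gene.strand == "+":
            w0, w1 = gene.tss - 10_000, gene.tss + 3_000
        else:
            w0, w1 = gene.tss - 3_000, gene.tss + 10_000
        expected = sum(
            r.fold_enrichment
            for r in peaks.itertuples(index=False)
            if r.chrom == gene.chrom and r.start < w1 and w0 < r.end
        )
        assert scores[gene.gene_id] == pytest.approx(expected, abs=1e-9)


def test_promoter_score_additive_over_peak_subsets(sim_tiny):
    peaks = sim_tiny.binding.chip_peaks
    half = len(peaks) // 2
    s_all = score_chip_promoter(peaks, sim_tiny.models)
    s1 = score_chip_promoter(peaks.iloc[:half], sim_tiny.models)
    s2 = score_chip_promoter(peaks.iloc[half:], sim_tiny.models)
    pd.testing.assert_series_equal(s_all, s1 + s2)


# ---------------------------------------------------------------------------
# Overlap test and coexpression screen
# ---------------------------------------------------------------------------

def test_hypergeometric_overlap_boundaries():
    u = set(range(20))
    assert hypergeometric_overlap(u, u, u) == 1.0
    a, b = set(range(10)), set(range(10, 20))
    assert hypergeometric_overlap(a, b, u) == 1.0  # >= 0 overlap is certain
    with pytest.raises(ValueError, match="universe"):
        hypergeometric_overlap({99}, a, u)
    with pytest.raises(ValueError, match="empty"):
        hypergeometric_overlap(set(), set(), set())


def test_pearson_coexpression_screen():
    rng = np.random.default_rng(4)
    anchor = rng.normal(size=20)
    mat = pd.DataFrame(
        {
            "anchor": anchor,
            "same": anchor.copy(),
            "anti": -anchor,
            "noise": rng.normal(size=20),
            "flat": np.ones(20),
        }
    ).T
    mat.columns = [f"s{i}" for i in range(20)]
    with pytest.warns(UserWarning, match="zero-variance"):
        hits = pearson_coexpression(mat, "anchor", threshold=0.3)
    assert hits["same"] == pytest.approx(1.0)
    assert hits["anti"] == pytest.approx(-1.0)
    assert "flat" not in hits.index
    assert "anchor" not in hits.index


def test_pearson_matches_covariance_formula():
    rng = np.random.default_rng(9)
    mat = pd.DataFrame(rng.normal(size=(50, 20)),
                       index=[f"g{i}" for i in range(50)],
                       columns=[f"s{i}" for i in range(20)])
    hits = pearson_coexpression(mat, "g0", threshold=0.0)
    x = mat.loc["g0"].to_numpy()
    for g in hits.index:
        y = mat.loc[g].to_numpy()
        expected = np.corrcoef(x, y)[0, 1]
        assert hits[g] == pytest.approx(expected, abs=1e-12)


def test_pearson_needs_enough_samples():
    mat = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["s1", "s2"])
    with pytest.raises(ValueError, match="samples"):
        pearson_coexpression(mat, "a")


def test_tukey_pair_lookup():
    ordering, p_sw, _ = tier_effect_trial(seed=5, n_per_tier=50)
    assert 0.0 <= p_sw <= 1.0
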