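"""Event classification topologies, IR criteria, and RASE statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipsplice import splicing as sp
from clipsplice.evaluate import junction_event_recovery, ir_recovery
from clipsplice.io import CoverageTrack
from clipsplice.models import GeneModel, Interval, Transcript


def gene_with_exons(exons, strand="+", gene_id="g1"):
    return GeneModel(
        gene_id, "chr1", strand, [Transcript(f"{gene_id}.t", [Interval(*e) for e in exons])]
    )


def junction_df(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "donor_end", "acceptor_start", "strand", "count", "sample"]
    )


def test_cassette_topology_single_skip_is_es():
    """Junctions {e1->e2, e2->e3} vs {e1->e3}: one skipping event, alt = e1->e3."""
    gene = gene_with_exons([(0, 100), (200, 300), (400, 500)])
    junctions = junction_df(
        [
            ("chr1", 100, 200, "+", 50, "s1"),
            ("chr1", 300, 400, "+", 50, "s1"),
            ("chr1", 100, 400, "+", 30, "s1"),
        ]
    )
    det = sp.detect_junction_events([gene], junctions)
    (ev,) = det.events
    assert ev.etype == sp.ES
    assert ev.alt_junctions == ((100, 400),)
    assert set(ev.model_junctions) == {(100, 200), (300, 400)}


def test_multi_exon_skip_is_cassette():
    gene = gene_with_exons([(0, 100), (200, 300), (400, 500), (600, 700)])
    junctions = junction_df(
        [
            ("chr1", 100, 200, "+", 50, "s1"),
            ("chr1", 300, 400, "+", 50, "s1"),
            ("chr1", 500, 600, "+", 50, "s1"),
            ("chr1", 100, 600, "+", 30, "s1"),
        ]
    )
    det = sp.detect_junction_events([gene], junctions)
    (ev,) = det.events
    assert ev.etype == sp.CASSETTE


def test_shared_donor_two_acceptors_is_a3ss_on_plus():
    gene = gene_with_exons([(0, 100), (200, 300)])
    junctions = junction_df(
        [
            ("chr1", 100, 200, "+", 60, "s1"),
            ("chr1", 100, 170, "+", 40, "s1"),  # acceptor 30 nt upstream
        ]
    )
    det = sp.detect_junction_events([gene], junctions)
    (ev,) = det.events
    assert ev.etype == sp.A3SS


def test_shared_donor_two_acceptors_is_a5ss_on_minus():
    gene = gene_with_exons([(0, 100), (200, 300)], strand="-")
    junctions = junction_df(
        [
            ("chr1", 100, 200, "-", 60, "s1"),
            ("chr1", 100, 170, "-", 40, "s1"),
        ]
    )
    det = sp.detect_junction_events([gene], junctions)
    (ev,) = det.events
    assert ev.etype == sp.A5SS


def test_mxe_requires_silent_connecting_junction():
    exons = [(0, 100), (200, 300), (400, 500), (600, 700)]
    gene = gene_with_exons(exons)
    base = [
        ("chr1", 100, 200, "+", 50, "s1"),  # e0->e1
        ("chr1", 500, 600, "+", 50, "s1"),  # e2->e3
        ("chr1", 100, 400, "+", 40, "s1"),  # skip e1
        ("chr1", 300, 600, "+", 40, "s1"),  # skip e2
    ]
    det = sp.detect_junction_events([gene], junction_df(base))
    (ev,) = det.events
    assert ev.etype == sp.MXE
    # with the connecting junction expressed the pair is two skip events
    with_connect = base + [("chr1", 300, 400, "+", 45, "s1")]
    det2 = sp.detect_junction_events([gene], junction_df(with_connect))
    assert sorted(e.etype for e in det2.events) == [sp.ES, sp.ES]


def test_orphan_junctions_reported_not_dropped():
    gene = gene_with_exons([(0, 100), (200, 300)])
    junctions = junction_df(
        [
            ("chr1", 100, 200, "+", 10, "s1"),
            ("chr9", 100, 200, "+", 7, "s1"),  # no host gene
        ]
    )
    det = sp.detect_junction_events([gene], junctions)
    assert len(det.orphans) == 1
    assert det.orphans.iloc[0]["chrom"] == "chr9"


def test_planted_events_recovered_with_correct_types(sim_study, sim_study_analysis):
    """>= 95% of planted junction events detected with the correct label."""
    rec = junction_event_recovery(
        sim_study, sim_study_analysis["rase"], sim_study_analysis["detection"].events
    )
    assert rec["n_planted"] >= 50
    assert rec["detection_rate"] >= 0.95


# ---------------------------------------------------------------------------
# Intron retention
# ---------------------------------------------------------------------------

def make_coverage(gene, exon_depth, intron_depths):
    t = gene.primary_transcript
    arr = np.zeros(t.span.end + 10)
    for e in t.exons:
        arr[e.start : e.end] = exon_depth
    for iv, d in zip(t.introns, intron_depths):
        arr[iv.start : iv.end] = d
    return CoverageTrack({"chr1": arr})


def test_ir_thresholds_applied():
    """Depth 30 vs flank 100 and baseline 5 is called; depth 15 is not."""
    gene = gene_with_exons([(0, 100), (200, 300), (400, 500), (600, 700)])
    cov = make_coverage(gene, 100, [30, 5, 5])
    called = sp.call_intron_retention([gene], cov)
    assert [e.intron for e in called] == [Interval(100, 200)]
    cov2 = make_coverage(gene, 100, [15, 5, 5])
    assert sp.call_intron_retention([gene], cov2) == []


def test_ir_requires_boundary_evidence():
    gene = gene_with_exons([(0, 100), (200, 300), (400, 500), (600, 700)])
    cov = make_coverage(gene, 100, [30, 5, 5])
    # erase the candidate's first and last intronic bases
    cov.arrays["chr1"][100] = 0
    cov.arrays["chr1"][199] = 0
    assert sp.call_intron_retention([gene], cov) == []


def test_ir_model_gene_baseline_blocks_uniformly_covered_introns():
    """All introns equally deep: each fails the 2x gene-baseline criterion."""
    gene = gene_with_exons([(0, 100), (200, 300), (400, 500), (600, 700)])
    cov = make_coverage(gene, 100, [30, 30, 30])
    assert sp.call_intron_retention([gene], cov) == []


def test_ir_intensity_values():
    assert sp.compute_ir_intensity(np.full(10, 10.0), np.full(10, 50.0)) == pytest.approx(0.2)
    assert sp.compute_ir_intensity(np.zeros(10), np.full(10, 50.0)) == 0.0
    assert np.isnan(sp.compute_ir_intensity(np.full(10, 5.0), np.zeros(10)))


def test_planted_ir_recovery(sim_study, sim_study_analysis):
    rec = ir_recovery(sim_study, sim_study_analysis["ir_events"], sim_study_analysis["rase"])
    assert rec["ir_sensitivity"] >= 0.9
    assert rec["ir_false_call_rate"] <= 0.05
    assert rec["ir_intensity_max_abs_error"] <= 0.05


# ---------------------------------------------------------------------------
# RASE statistics
# ---------------------------------------------------------------------------

def test_rase_identical_proportions():
    p, ratio, sig, degen = sp.rase_test(10, 90, 10, 90)
    assert p == 1.0 and ratio == 0.0 and not sig and not degen


def test_rase_ratio_exact_and_p_matches_enumeration():
    from fractions import Fraction
    from math import comb

    p, ratio, sig, _ = sp.rase_test(30, 70, 10, 90)
    assert ratio == pytest.approx(0.2, abs=1e-15)
    # exhaustive enumeration over tables with the same margins
    denom = comb(200, 40)
    p_obs = Fraction(comb(100, 30) * comb(100, 10), denom)
    total = Fraction(0)
    for t in range(0, 41):
        pt = Fraction(comb(100, t) * comb(100, 40 - t), denom)
        if pt <= p_obs:
            total += pt
    assert p == pytest.approx(float(total), abs=1e-12)
    assert not sig  # ratio must exceed 0.2 strictly


def test_rase_degenerate_all_zero():
    p, ratio, sig, degen = sp.rase_test(0, 0, 0, 0)
    assert p == 1.0 and ratio == 0.0 and degen and not sig


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 80), st.integers(0, 80), st.integers(0, 80), st.integers(0, 80))
def test_rase_symmetric_under_condition_exchange(a, b, c, d):
    p1, r1, _, _ = sp.rase_test(a, b, c, d)
    p2, r2, _, _ = sp.rase_test(c, d, a, b)
    assert p1 == p2
    assert r1 == pytest.approx(r2, abs=1e-15)


def test_significance_thresholds():
    # strong effect at decent depth: significant
    p, ratio, sig, _ = sp.rase_test(60, 40, 20, 80)
    assert sig and p < 0.05 and ratio > 0.2
    # large ratio but almost no reads: not significant
    p2, _, sig2, _ = sp.rase_test(1, 1, 0, 2)
    assert not sig2 and p2 > 0.05


def test_differential_table_fdr_mode(sim_study, sim_study_analysis):
    rase = sp.differential_splicing(
        sim_study_analysis["events"],
        sim_study.junctions,
        sim_study.samples,
        coverage=sim_study_analysis["cond_cov"],
        significance="fdr",
    )
    assert "q_value" in rase.columns
    assert (rase["q_value"] >= rase["p_value"] - 1e-12).all()
    assert rase.loc[rase["significant"], "rase_ratio"].min() > 0.2
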