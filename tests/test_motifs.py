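"""Motif scanning vs brute force, regional frequencies, binning, metagene."""

import numpy as np
import pandas as pd
import pytest

from clipsplice.io import CoverageTrack
from clipsplice.models import GeneModel, Interval, Transcript
from clipsplice.motifs import (
    BUILTIN_PATTERNS,
    bin_by_motif_count,
    metagene_boundary_profile,
    parse_pattern,
    region_motif_frequency,
    reverse_complement,
    scan_motif,
    scan_u_rich,
    transcript_motif_counts,
)


def brute_force_scan(sequence, pattern):
    """Position-by-position matcher, written independently of the package."""
    allowed = []
    i = 0
    pat = pattern.upper().replace("U", "T")
    while i < len(pat):
        if pat[i] == "[":
            j = pat.index("]", i)
            allowed.append(set(pat[i + 1 : j]))
            i = j + 1
        elif pat[i] == "N":
            allowed.append(set("ACGT"))
            i += 1
        else:
            allowed.append({pat[i]})
            i += 1
    seq = sequence.upper()
    hits = []
    for s in range(len(seq) - len(allowed) + 1):
        if all(seq[s + k] in allowed[k] for k in range(len(allowed))):
            hits.append(s)
    return hits


def test_rna_alphabet_matches_dna():
    assert scan_motif("AGGTAAG", "AGGUAAG") == [0]
    assert scan_motif("TGGAC", "UGGAC") == [0]


def test_overlapping_hits_counted():
    assert scan_motif("GAAGAAGAA", "GAAGAA") == [0, 3]


def test_minus_strand_scans_reverse_complement():
    seq = reverse_complement("AGGTAAG")
    assert scan_motif(seq, "AGGUAAG", strand="-") == [0]
    assert scan_motif(seq, "AGGUAAG", strand="+") == []


def test_empty_pattern_rejected():
    with pytest.raises(ValueError, match="empty"):
        scan_motif("ACGT", "")


def test_degenerate_patterns_match_brute_force_on_random_sequence():
    rng = np.random.default_rng(77)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
    for pattern in BUILTIN_PATTERNS.values():
        assert scan_motif(seq, pattern) == brute_force_scan(seq, pattern)


def test_u_rich_window_rule():
    assert scan_u_rich("TTTTTT") == [0]
    assert scan_u_rich("TTTTAT") == [0]  # 5 of 6
    assert scan_u_rich("TTTAAT") == []
    assert scan_u_rich("ATTTTTTA") == [0, 1, 2]


def test_parse_pattern_classes():
    assert parse_pattern("[GA]GN") == [frozenset("GA"), frozenset("G"), frozenset("ACGT")]


# ---------------------------------------------------------------------------
# Regional frequencies
# ---------------------------------------------------------------------------

def test_region_frequency_extremes():
    genome = {"chr1": "A" * 50 + "GAAGAA" + "A" * 44 + "C" * 100}
    peaks = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [40, 100],
            "end": [70, 130],
            "name": ["p1", "p2"],
            "fold_enrichment": [2.0, 2.0],
            "strand": ["+", "+"],
            "region": ["CDS", "intron"],
        }
    )
    freq = region_motif_frequency(peaks, genome, {"ESE": "GAAGAA"})
    by_region = freq.set_index("region")
    assert by_region.loc["CDS", "proportion"] == 1.0
    assert by_region.loc["intron", "proportion"] == 0.0


def test_region_frequency_requires_annotation():
    with pytest.raises(ValueError, match="region"):
        region_motif_frequency(pd.DataFrame({"chrom": []}), {}, {})


def test_seeded_boundary_motif_enriched_at_boundaries(sim_study):
    """5'ss-motif peaks make boundary peaks richer in AGGUAAG than intron ones."""
    from clipsplice.regions import RegionAnnotator

    annotated = RegionAnnotator(sim_study.models).annotate_peaks(
        sim_study.binding.clip_peaks
    )
    freq = region_motif_frequency(annotated, sim_study.genome,
                                  {"5ss": "AGGUAAG"})
    by_region = freq.set_index("region")["proportion"]
    assert by_region["exon-intron boundary"] > by_region.get("intron", 0.0)


# ---------------------------------------------------------------------------
# 11-bin analysis
# ---------------------------------------------------------------------------

def test_top_bin_collapse():
    counts = pd.Series(range(13), index=[f"g{i}" for i in range(13)])
    signal = pd.Series(np.ones(13), index=counts.index)
    summary, _ = bin_by_motif_count(counts, signal)
    assert summary["n"].tolist() == [1] * 10 + [3]


def test_single_occupied_bin():
    counts = pd.Series([0, 0, 0], index=list("abc"))
    signal = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    summary, rho = bin_by_motif_count(counts, signal)
    assert summary.loc[0, "n"] == 3
    assert summary["n"].sum() == 3
    assert np.isnan(rho)


def test_planted_monotone_signal_recovered():
    rng = np.random.default_rng(21)
    n = 3000
    counts = pd.Series(rng.integers(0, 13, n), index=[f"g{i}" for i in range(n)])
    signal = 50.0 * (counts + 1) * np.exp(rng.normal(0, 0.2, n))
    summary, rho = bin_by_motif_count(counts, pd.Series(signal, index=counts.index))
    occupied = summary[summary["n"] > 0]
    assert (occupied["median"].diff().dropna() >= 0).all()
    assert rho > 0.9


def test_simulated_binding_bins_monotone(sim_study):
    truth = sim_study.truth.genes
    bound = truth.index[truth["bound"]]
    _, rho = bin_by_motif_count(
        truth.loc[bound, "motifs_total"], sim_study.binding.clip_signal.loc[bound]
    )
    assert rho > 0.9


def test_transcript_motif_counts_cover_planted(sim_tiny):
    counts = transcript_motif_counts(sim_tiny.models, sim_tiny.genome)
    truth = sim_tiny.truth.genes
    assert (counts["5ss_AGGUAAG"] >= truth["motifs_AGGTAAG"]).all()
    assert (counts["ESE_GAAGAA"] >= truth["motifs_GAAGAA"]).all()


# ---------------------------------------------------------------------------
# Metagene
# ---------------------------------------------------------------------------

def three_exon_gene(gene_id="g1", strand="+", offset=0):
    exons = [Interval(offset, offset + 150), Interval(offset + 650, offset + 800),
             Interval(offset + 1300, offset + 1450)]
    return GeneModel(gene_id, "chr1", strand, [Transcript(f"{gene_id}.t", exons)])


def test_uniform_depth_profile_is_flat_one():
    gene = three_exon_gene()
    cov = CoverageTrack({"chr1": np.full(1500, 10.0)})
    prof = metagene_boundary_profile({"RNA": cov}, [gene], peak_genes=set())
    key = "RNA|nonpeak"
    assert prof.profiles[key].max() == pytest.approx(1.0)
    assert prof.profiles[key].min() == pytest.approx(1.0)
    assert prof.n_genes[key] == 1


def test_global_max_normalization_across_groups():
    g1 = three_exon_gene("g1")
    g2 = three_exon_gene("g2", offset=2000)
    arr = np.full(4000, 5.0)
    arr[2000:] = 20.0  # g2 dominates
    cov = CoverageTrack({"chr1": arr})
    prof = metagene_boundary_profile({"RNA": cov}, [g1, g2], peak_genes={"g2"})
    assert prof.profiles["RNA|peak"].max() == pytest.approx(1.0)
    assert prof.profiles["RNA|nonpeak"].max() < 1.0


def test_profile_invariant_under_uniform_scaling():
    gene = three_exon_gene()
    rng = np.random.default_rng(2)
    arr = rng.poisson(10, 1500).astype(float)
    p1 = metagene_boundary_profile(
        {"RNA": CoverageTrack({"chr1": arr})}, [gene], set()
    )
    p2 = metagene_boundary_profile(
        {"RNA": CoverageTrack({"chr1": arr * 3.7})}, [gene], set()
    )
    for key in p1.profiles:
        np.testing.assert_allclose(p1.profiles[key], p2.profiles[key], rtol=1e-12)


def test_genes_without_internal_exons_excluded():
    gene = GeneModel("g1", "chr1", "+",
                     [Transcript("t", [Interval(0, 100), Interval(200, 300)])])
    cov = CoverageTrack({"chr1": np.full(300, 4.0)})
    with pytest.raises(ValueError, match="no coverage"):
        metagene_boundary_profile({"RNA": cov}, [gene], set())


def test_planted_splice_site_peaks_raise_clip_profile(sim_study):
    from clipsplice.io import pool_tracks

    rna = pool_tracks([sim_study.coverage[s] for s in sim_study.samples["control"]])
    peak_genes = set(
        sim_study.truth.genes.index[sim_study.truth.genes["bound"]]
    )
    prof = metagene_boundary_profile(
        {"CLIP": sim_study.binding.clip_track, "RNA": rna},
        sim_study.models,
        peak_genes,
    )
    a5 = prof.anchor_5ss
    window = slice(a5 - 20, a5 + 20)
    assert (
        prof.profiles["CLIP|peak"][window].mean()
        > prof.profiles["CLIP|nonpeak"][window].mean()
    )
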