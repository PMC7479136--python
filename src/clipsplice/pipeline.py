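"""End-to-end orchestration: simulate -> detect -> test -> stratify -> report.

The pipeline runs on the synthetic dataset (or user-supplied files loaded
through :mod:`clipsplice.io`), executes the stages in dependency order, and
writes a machine-readable result bundle: one TSV per result table with a
JSON sidecar declaring its column schema, a manifest with the config
snapshot and software version, and a log with one record (including input
checksums) per stage. All outputs are deterministic under a fixed seed, so
re-running a bundle's config reproduces it byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from . import __version__
from .affinity import (
    clip_signal_from_peaks,
    ecdf_shift_analysis,
    hypergeometric_overlap,
    score_chip_promoter,
    score_clip_affinity,
    tier_genes,
)
from .io import CoverageTrack, compute_fpkm, log2_fold_change, pool_tracks
from .motifs import (
    bin_by_motif_count,
    metagene_boundary_profile,
    region_motif_frequency,
    transcript_motif_counts,
)
from .regions import RegionAnnotator
from .simulate import SimConfig, SimData, simulate_all, write_simulation
from .splicing import call_intron_retention, detect_junction_events, differential_splicing

ALL_STAGES = (
    "simulate", "expression", "splicing", "binding", "motifs", "metagene", "overlaps"
)

AS_RATIO_PSEUDO = 0.01  # pseudocount on alternative-read proportions


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "clipsplice_run"
    p_threshold: float = 0.05
    ratio_threshold: float = 0.2
    significance: str = "pvalue"  # or 'fdr'
    fdr_threshold: float = 0.01
    deg_lfc_threshold: float = 1.0
    deg_p_threshold: float = 0.05
    pcc_threshold: float = 0.3
    promoter_up: int = 10_000
    promoter_down: int = 3_000
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold outside (0, 1)")
        if not 0 <= self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold outside [0, 1]")
        if self.significance not in ("pvalue", "fdr"):
            raise ValueError("significance must be 'pvalue' or 'fdr'")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.sim.validate()


@dataclass
class ResultBundle:
    outdir: Path
    tables: dict[str, pd.DataFrame]
    data: SimData
    log: list[dict]


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _write_table(outdir: Path, name: str, df: pd.DataFrame, index: bool = False) -> Path:
    path = outdir / f"{name}.tsv"
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    schema = {
        "table": name,
        "columns": ([df.index.name] if index else []) + list(map(str, df.columns)),
    }
    (outdir / f"{name}.schema.json").write_text(json.dumps(schema, indent=2) + "\n")
    return path


def deg_screen(
    gene_counts: pd.DataFrame,
    log2fc: pd.Series,
    samples: dict[str, list[str]],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Differential-abundance screen on pooled counts.

    An exact two-sided binomial test compares each gene's pooled treated
    count against the library-size expectation, combined with a |log2FC|
    cutoff. A deliberately simple stand-in for count-model machinery: the
    downstream overlap and ECDF stages only need a gene set and fold
    changes.
    """
    ctrl = gene_counts[samples["control"]].sum(axis=1)
    trt = gene_counts[samples["treated"]].sum(axis=1)
    lib_c, lib_t = ctrl.sum(), trt.sum()
    p_expected = lib_t / (lib_t + lib_c)
    pvals = np.array([
        sstats.binomtest(int(t), int(t + c), p_expected).pvalue if t + c > 0 else 1.0
        for t, c in zip(trt, ctrl)
    ])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    crit = qvals < p_threshold if use_fdr else pvals < p_threshold
    return pd.DataFrame(
        {
            "count_control": ctrl,
            "count_treated": trt,
            "log2fc": log2fc.reindex(gene_counts.index),
            "p_value": pvals,
            "q_value": qvals,
            "significant": crit & (log2fc.reindex(gene_counts.index).abs() >= lfc_threshold),
        }
    )


def as_ratio_log2fc(rase: pd.DataFrame, pseudo: float = AS_RATIO_PSEUDO) -> pd.Series:
    """Per-gene log2 change of the AS ratio, from the gene's largest-|effect|
    event (alternative-read proportion treated vs control)."""
    if rase.empty:
        return pd.Series(dtype=float, name="as_log2fc")
    df = rase.loc[rase.groupby("gene_id")["rase_ratio"].idxmax()]
    prop_c = df["alt_control"] / (df["alt_control"] + df["model_control"]).clip(lower=1)
    prop_t = df["alt_treated"] / (df["alt_treated"] + df["model_treated"]).clip(lower=1)
    vals = np.log2((prop_t + pseudo) / (prop_c + pseudo))
    return pd.Series(vals.to_numpy(), index=df["gene_id"], name="as_log2fc")


def summarize_overlaps(
    rase_genes: set[str],
    deg_genes: set[str],
    clip_genes: set[str],
    chip_genes: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Pairwise intersections, fractions, and hypergeometric p-values."""
    sets = {
        "RASG": set(rase_genes),
        "DEG": set(deg_genes),
        "CLIP_bound": set(clip_genes),
        "ChIP_promoter": set(chip_genes),
    }
    for name, s in sets.items():
        stray = s - universe
        if stray:
            raise ValueError(f"{name} not contained in universe: {sorted(stray)[:5]}")
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = sets[a] & sets[b]
            rows.append(
                dict(
                    set_a=a, set_b=b, n_a=len(sets[a]), n_b=len(sets[b]),
                    n_overlap=len(inter),
                    fraction_of_a=len(inter) / len(sets[a]) if sets[a] else np.nan,
                    fraction_of_b=len(inter) / len(sets[b]) if sets[b] else np.nan,
                    p_hypergeom=hypergeometric_overlap(sets[a], sets[b], universe),
                )
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ResultBundle:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    log: list[dict] = []
    stage_set = set(config.stages)

    def record(stage: str, inputs: Sequence[Path] = (), **extra) -> None:
        log.append(
            dict(stage=stage,
                 inputs={p.name: _md5(p) for p in inputs},
                 **extra)
        )

    try:
        # --- simulate ------------------------------------------------------
        data = simulate_all(config.sim)
        simdir = outdir / "sim"
        if "simulate" in stage_set:
            write_simulation(data, simdir)
            record("simulate", sorted(simdir.glob("*.tsv")),
                   n_genes=len(data.models))
        samples = data.samples
        models = data.models

        # --- expression ----------------------------------------------------
        expression = None
        if "expression" in stage_set:
            fpkm = compute_fpkm(data.gene_counts, models)
            lfc = log2_fold_change(fpkm, samples["treated"], samples["control"])
            expression = deg_screen(
                data.gene_counts, lfc, samples,
                config.deg_lfc_threshold, config.deg_p_threshold,
                use_fdr=config.significance == "fdr",
            )
            expression = expression.join(
                fpkm.add_prefix("fpkm_"), how="left"
            )
            tables["expression"] = expression
            _write_table(outdir, "expression", expression, index=True)
            record("expression", [outdir / "expression.tsv"])

        # --- splicing ------------------------------------------------------
        rase = None
        if "splicing" in stage_set:
            det = detect_junction_events(models, data.junctions)
            cond_cov = {
                cond: pool_tracks([data.coverage[s] for s in names])
                for cond, names in samples.items()
            }
            ir_events = {}
            for cond, cov in sorted(cond_cov.items()):
                for ev in call_intron_retention(models, cov):
                    ir_events[ev.event_id] = ev
            events = det.events + [ir_events[k] for k in sorted(ir_events)]
            rase = differential_splicing(
                events, data.junctions, samples, coverage=cond_cov,
                read_length=config.sim.read_length,
                p_threshold=config.p_threshold,
                ratio_threshold=config.ratio_threshold,
                significance=config.significance,
                fdr_threshold=config.fdr_threshold,
            )
            tables["rase"] = rase
            _write_table(outdir, "rase", rase)
            event_table = pd.DataFrame(
                [
                    dict(event_id=e.event_id, gene_id=e.gene_id, type=e.etype,
                         chrom=e.chrom, strand=e.strand,
                         span_start=e.span[0], span_end=e.span[1],
                         model_junctions=";".join(f"{l}-{r}" for l, r in e.model_junctions),
                         alt_junctions=";".join(f"{l}-{r}" for l, r in e.alt_junctions))
                    for e in events
                ]
            ).sort_values("event_id", ignore_index=True)
            tables["events"] = event_table
            _write_table(outdir, "events", event_table)
            tables["unclassified_junctions"] = det.unclassified
            _write_table(outdir, "unclassified_junctions", det.unclassified)
            record("splicing", [outdir / "rase.tsv", outdir / "events.tsv"],
                   n_events=len(events),
                   n_unclassified=len(det.unclassified),
                   n_orphans=len(det.orphans))

        # --- binding affinity ---------------------------------------------
        affinity_table = None
        if "binding" in stage_set:
            if expression is None:
                raise ValueError("binding stage requires the expression stage")
            fpkm_ctrl = expression[[f"fpkm_{s}" for s in samples["control"]]].mean(axis=1)
            signal = clip_signal_from_peaks(data.binding.clip_peaks, models)
            aff = score_clip_affinity(signal, fpkm_ctrl)
            aff = tier_genes(aff, mode="clip")
            chip = score_chip_promoter(
                data.binding.chip_peaks, models,
                config.promoter_up, config.promoter_down,
            )
            aff["chip_promoter_score"] = chip.reindex(aff.index).fillna(0.0)
            if (aff["chip_promoter_score"] > 0).sum() >= 3:
                aff = tier_genes(aff, mode="chip")
            else:
                aff["chip_tier"] = "unbound"
            affinity_table = aff
            tables["affinity"] = aff
            _write_table(outdir, "affinity", aff, index=True)

            responses = {"abundance": expression["log2fc"]}
            if rase is not None:
                responses["splicing"] = as_ratio_log2fc(rase)
            ecdf_rows = []
            for resp_name, resp in responses.items():
                for mode, tier_col in (("clip", "clip_tier"), ("chip", "chip_tier")):
                    try:
                        cmp_ = ecdf_shift_analysis(aff, resp, tier_col=tier_col)
                    except ValueError:
                        continue
                    for tier, med in cmp_.medians.items():
                        ecdf_rows.append(
                            dict(response=resp_name, mode=mode, tier=tier,
                                 n=len(cmp_.tier_values[tier]), median=med,
                                 anova_f=cmp_.anova_f, anova_p=cmp_.anova_p,
                                 ks_strong_weak=cmp_.ks_stat, ks_p=cmp_.ks_p)
                        )
            ecdf_table = pd.DataFrame(ecdf_rows)
            tables["ecdf"] = ecdf_table
            _write_table(outdir, "ecdf", ecdf_table)
            record("binding", [outdir / "affinity.tsv", outdir / "ecdf.tsv"])

        # --- motifs ---------------------------------------------------------
        if "motifs" in stage_set:
            annotator = RegionAnnotator(models)
            clip_annot = annotator.annotate_peaks(data.binding.clip_peaks)
            freq = region_motif_frequency(clip_annot, data.genome)
            tables["motif_region_frequency"] = freq
            _write_table(outdir, "motif_region_frequency", freq)
            motif_counts = transcript_motif_counts(models, data.genome)
            signal = data.binding.clip_signal
            bound = signal.index[signal > 0]
            bins, rho = bin_by_motif_count(
                motif_counts.loc[bound, "total"], signal.loc[bound]
            )
            bins["spearman_rho"] = rho
            tables["motif_bins"] = bins
            _write_table(outdir, "motif_bins", bins)
            record("motifs", [outdir / "motif_region_frequency.tsv"],
                   spearman_rho=rho)

        # --- metagene -------------------------------------------------------
        if "metagene" in stage_set:
            rna = pool_tracks([data.coverage[s] for s in samples["control"]])
            peak_genes = set(
                clip_signal_from_peaks(data.binding.clip_peaks, models)
                .pipe(lambda s: s[s > 0])
                .index
            )
            prof = metagene_boundary_profile(
                {"CLIP": data.binding.clip_track, "RNA": rna}, models, peak_genes
            )
            mg = prof.to_frame()
            tables["metagene"] = mg
            _write_table(outdir, "metagene", mg, index=True)
            record("metagene", [outdir / "metagene.tsv"],
                   n_genes=prof.n_genes)

        # --- overlaps -------------------------------------------------------
        if "overlaps" in stage_set and rase is not None and expression is not None:
            universe = {g.gene_id for g in models}
            rasg = set(rase.loc[rase["significant"], "gene_id"])
            deg = set(expression.index[expression["significant"]])
            clip_bound = set(data.binding.clip_peaks["name"].str.split("_").str[1])
            chip_prom = (
                set(affinity_table.index[affinity_table["chip_promoter_score"] > 0])
                if affinity_table is not None
                else set()
            )
            overlaps = summarize_overlaps(rasg, deg, clip_bound, chip_prom, universe)
            tables["overlaps"] = overlaps
            _write_table(outdir, "overlaps", overlaps)
            record("overlaps", [outdir / "overlaps.tsv"],
                   n_rasg=len(rasg), n_deg=len(deg))
    except Exception as err:  # partial failure: machine-readable record
        (outdir / "failure.json").write_text(
            json.dumps({"error": type(err).__name__, "message": str(err)}, indent=2)
            + "\n"
        )
        raise

    manifest = {
        "version": __version__,
        "config": _config_dict(config),
        "stages": log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return ResultBundle(outdir=outdir, tables=tables, data=data, log=log)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["affinity_effect"] = dict(d["sim"]["affinity_effect"])
    d["sim"]["motif_seeding"] = dict(d["sim"]["motif_seeding"])
    d["stages"] = list(d["stages"])
    return d
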