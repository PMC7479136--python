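"""Miniature two-condition transcriptome simulator with planted ground truth.

Emulates the statistical structure of a knockout-vs-control study of an
RNA-binding chromatin-associated protein: a small genome with multi-exon
genes (canonical GT..AG introns, seeded splicing motifs), per-sample splice
junction counts and per-base coverage for two conditions x replicates,
planted differential expression and alternative-splicing switches of all
eight event types (including intron retention), CLIP peaks centered on
seeded motifs with per-gene binding signal increasing in motif count, and
ChIP peaks inside/outside promoter windows. Every planted effect is
recorded in a :class:`SimTruth` table that round-trips losslessly through
TSV.

Junction counts are Poisson around depth x isoform usage (negative-binomial
overdispersion is available but off by default); a gene's emitted read
count is the exact sum of its junction counts, so count conservation holds
by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import splicing as sp
from .io import (
    CoverageTrack,
    write_annotation,
    write_fasta,
    write_gene_counts,
    write_junctions,
    write_peaks,
)
from .models import GeneModel, Interval, Transcript
from .motifs import reverse_complement

EXONIC_PATTERNS = {"GAAGAA": "GAAGAA", "TGGAC": "TGGAC"}
FIVE_SS_SEED = "AGGTAAG"  # AG|GTAAG across the exon/intron border
U_RICH_SEED = "TTTTTT"

EVENT_CYCLE = (
    sp.CASSETTE, sp.ES, sp.MXE, sp.A5SS, sp.A3SS, sp.MXE5P, sp.MXE3P, sp.INTRON_R
)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic dataset."""

    seed: int = 0
    n_genes: int = 60
    n_chroms: int = 2
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (600, 1200)
    intergenic_len: tuple[int, int] = (400, 900)
    n_replicates: int = 2
    mean_depth: float = 200.0
    depth_spread: tuple[float, float] = (0.6, 1.6)
    frac_de: float = 0.25
    de_log2fc: float = 1.5
    frac_as: float = 0.4
    base_psi: float = 0.5
    delta_psi: float = 0.4
    ir_fraction: float = 0.3
    intron_background: float = 0.02
    frac_bound: float = 0.6
    frac_as_bound: float = 0.8
    affinity_effect: Mapping[str, float] = field(
        default_factory=lambda: {"strong": 0.5, "median": 0.25, "weak": 0.0}
    )
    motif_seeding: Mapping[str, float] = field(
        default_factory=lambda: {
            "AGGTAAG": 1.5, "GAAGAA": 2.5, "TGGAC": 1.5, "U_RICH": 1.0
        }
    )
    clip_signal_scale: float = 50.0
    clip_noise_sd: float = 0.2
    peak_halfwidth: int = 15
    frac_chip: float = 0.5
    chip_peaks_per_gene: tuple[int, int] = (1, 3)
    chip_fold_enrichment: tuple[float, float] = (2.0, 10.0)
    frac_chip_distal: float = 0.3
    read_length: int = 100
    overdispersion: float = 0.0

    def validate(self) -> None:
        for name in ("frac_de", "frac_as", "ir_fraction", "intron_background",
                     "frac_bound", "frac_as_bound", "frac_chip", "frac_chip_distal",
                     "base_psi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.delta_psi <= 1.0:
            raise ValueError("delta_psi outside [0, 1]")
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len",
                     "chip_peaks_per_gene"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range {name}=({lo}, {hi})")
        if self.exons_per_gene[0] < 4:
            raise ValueError("need >= 4 exons per gene to plant all event types")
        # splice-site motifs need GT..AG plus the seeded 5'ss/U-rich elements
        if self.intron_len[0] < 80:
            raise ValueError("introns too short to hold splice-site motifs")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate per condition")


@dataclass
class SimTruth:
    """Planted ground truth: per-gene effects, events, and motif placements."""

    genes: pd.DataFrame  # indexed by gene_id
    events: pd.DataFrame
    motifs: pd.DataFrame

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index_label="gene_id")
        self.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
        self.motifs.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, outdir: str | Path) -> "SimTruth":
        outdir = Path(outdir)
        return cls(
            genes=pd.read_csv(outdir / "truth_genes.tsv", sep="\t", index_col="gene_id"),
            events=pd.read_csv(outdir / "truth_events.tsv", sep="\t"),
            motifs=pd.read_csv(outdir / "truth_motifs.tsv", sep="\t"),
        )


@dataclass
class BindingData:
    clip_peaks: pd.DataFrame
    clip_signal: pd.Series
    chip_peaks: pd.DataFrame
    clip_track: CoverageTrack


@dataclass
class SimData:
    config: SimConfig
    genome: dict[str, str]
    models: list[GeneModel]
    truth: SimTruth
    junctions: pd.DataFrame
    coverage: dict[str, CoverageTrack]
    gene_counts: pd.DataFrame
    binding: BindingData

    @property
    def samples(self) -> dict[str, list[str]]:
        n = self.config.n_replicates
        return {
            "control": [f"control_{i + 1}" for i in range(n)],
            "treated": [f"treated_{i + 1}" for i in range(n)],
        }


# ---------------------------------------------------------------------------
# Reference + planted plan
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], SimTruth]:
    """Build the genome, gene models, and the full planted-truth plan."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    chrom_seqs: dict[str, list[str]] = {
        f"chrSim{i + 1}": [] for i in range(config.n_chroms)
    }
    cursors = {c: 0 for c in chrom_seqs}
    models: list[GeneModel] = []
    gene_rows = []
    motif_rows = []
    event_rows = []

    n = config.n_genes
    as_genes = _pick(rng, n, config.frac_as)
    de_genes = _pick(rng, n, config.frac_de)
    event_types = {g: EVENT_CYCLE[i % len(EVENT_CYCLE)] for i, g in enumerate(as_genes)}

    # motif counts per gene (drives CLIP binding signal)
    motif_plan = {
        gi: {
            pat: int(rng.poisson(lam))
            for pat, lam in sorted(config.motif_seeding.items())
        }
        for gi in range(n)
    }

    for gi in range(n):
        gene_id = f"gene{gi + 1:04d}"
        chrom = f"chrSim{gi % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        intron_lens = rng.integers(
            config.intron_len[0], config.intron_len[1] + 1, n_ex - 1
        )
        seq, exons_or, motifs_or, planted_counts = _build_gene_sequence(
            rng, exon_lens, intron_lens, motif_plan[gi]
        )
        spacer = int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
        chrom_seqs[chrom].append(_random_seq(rng, spacer))
        cursors[chrom] += spacer
        gene_start = cursors[chrom]
        gene_len = len(seq)
        if strand == "-":
            seq = reverse_complement(seq)
        chrom_seqs[chrom].append(seq)
        cursors[chrom] += gene_len

        exons = [
            _oriented_to_genomic(iv, gene_start, gene_len, strand) for iv in exons_or
        ]
        exons.sort()
        cds = _plan_cds(exons_or, gene_start, gene_len, strand)
        transcript = Transcript(f"{gene_id}.t1", exons, cds)
        gene = GeneModel(gene_id, chrom, strand, [transcript])
        models.append(gene)

        for pat, pos, length in motifs_or:
            if strand == "+":
                g_start = gene_start + pos
            else:
                g_start = gene_start + gene_len - pos - length
            motif_rows.append(
                dict(gene_id=gene_id, pattern=pat, chrom=chrom,
                     start=g_start, end=g_start + length, strand=strand)
            )

        depth_factor = float(
            rng.uniform(config.depth_spread[0], config.depth_spread[1])
        )
        lfc = 0.0
        if gi in de_genes:
            lfc = config.de_log2fc * (1.0 if rng.random() < 0.5 else -1.0)
        gene_rows.append(
            dict(
                chrom=chrom, strand=strand, tss=gene.tss,
                span_start=gene.span.start, span_end=gene.span.end,
                n_exons=n_ex, exonic_length=transcript.exonic_length,
                n_junctions=n_ex - 1,
                depth_factor=depth_factor, de=gi in de_genes, log2fc_de=lfc,
                event_type=event_types.get(gi, "none"),
                **{f"motifs_{p}": c for p, c in sorted(planted_counts.items())},
            )
        )
        gene_rows[-1]["motifs_total"] = sum(planted_counts.values())
        if gi in as_genes:
            event_rows.append(
                _plan_event(rng, config, gene, transcript, event_types[gi])
            )

    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}
    # trailing spacer keeps downstream windows inside the sequence
    tail_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
    for c in genome:
        genome[c] += _random_seq(tail_rng, 300)

    genes = pd.DataFrame(gene_rows, index=[g.gene_id for g in models])
    events = pd.DataFrame(event_rows) if event_rows else pd.DataFrame(
        columns=["gene_id", "type"]
    )
    truth = SimTruth(genes=genes, events=events, motifs=pd.DataFrame(
        motif_rows, columns=["gene_id", "pattern", "chrom", "start", "end", "strand"]
    ))
    _plan_binding(config, models, truth)
    return genome, models, truth


def _pick(rng: np.random.Generator, n: int, frac: float) -> set[int]:
    k = int(round(frac * n))
    return set(rng.choice(n, size=k, replace=False).tolist()) if k else set()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _build_gene_sequence(rng, exon_lens, intron_lens, motif_plan):
    """Assemble the gene in transcript orientation; seed motifs; return the
    sequence, oriented exon intervals, motif placements, and realized counts."""
    n_ex = len(exon_lens)
    exon_seqs = [_random_seq(rng, int(l)) for l in exon_lens]
    intron_seqs = []
    for l in intron_lens:
        body = _random_seq(rng, int(l) - 4)
        intron_seqs.append("GT" + body + "AG")
    counts = {p: 0 for p in motif_plan}

    # 5'ss consensus: exon ends with AG, intron starts with GTAAG
    n_5ss = min(motif_plan.get("AGGTAAG", 0), n_ex - 1)
    for k in rng.permutation(n_ex - 1)[:n_5ss]:
        exon_seqs[k] = exon_seqs[k][:-2] + "AG"
        intron_seqs[k] = "GTAAG" + intron_seqs[k][5:]
        counts["AGGTAAG"] += 1
    # U-rich element upstream of the 3'ss (near each intron's end)
    n_ur = min(motif_plan.get("U_RICH", 0), n_ex - 1)
    for k in rng.permutation(n_ex - 1)[:n_ur]:
        s = intron_seqs[k]
        pos = len(s) - 12
        intron_seqs[k] = s[:pos] + U_RICH_SEED + s[pos + len(U_RICH_SEED):]
        counts["U_RICH"] += 1
    # exon-body motifs (ESE and m6A context); colliding placements are skipped
    used: dict[int, list[tuple[int, int]]] = {k: [] for k in range(n_ex)}
    for pat in sorted(set(motif_plan) & set(EXONIC_PATTERNS)):
        for _ in range(motif_plan[pat]):
            k = int(rng.integers(0, n_ex))
            if len(exon_seqs[k]) < len(pat) + 20:
                continue
            pos = int(rng.integers(10, len(exon_seqs[k]) - len(pat) - 10))
            if any(pos < e and s < pos + len(pat) for s, e in used[k]):
                continue
            used[k].append((pos, pos + len(pat)))
            exon_seqs[k] = (
                exon_seqs[k][:pos] + pat + exon_seqs[k][pos + len(pat):]
            )
            counts[pat] += 1

    seq_parts = []
    exon_ivs = []
    intron_ivs = []
    cursor = 0
    for k in range(n_ex):
        exon_ivs.append(Interval(cursor, cursor + len(exon_seqs[k])))
        seq_parts.append(exon_seqs[k])
        cursor += len(exon_seqs[k])
        if k < n_ex - 1:
            intron_ivs.append(Interval(cursor, cursor + len(intron_seqs[k])))
            seq_parts.append(intron_seqs[k])
            cursor += len(intron_seqs[k])
    seq = "".join(seq_parts)
    # record oriented motif positions by scanning the constructed sequence
    # (chance occurrences of the exonic patterns are recorded too)
    motifs: list[tuple[str, int, int]] = []  # (pattern, oriented pos, len)
    for iv in exon_ivs[:-1]:
        if seq[iv.end - 2 : iv.end + 5] == FIVE_SS_SEED:
            motifs.append(("AGGTAAG", iv.end - 2, len(FIVE_SS_SEED)))
    for pat in sorted(EXONIC_PATTERNS):
        for iv in exon_ivs:
            sub = seq[iv.start : iv.end]
            start = 0
            while True:
                p = sub.find(pat, start)
                if p < 0:
                    break
                motifs.append((pat, iv.start + p, len(pat)))
                start = p + 1
    for iv in intron_ivs:
        sub = seq[iv.start : iv.end]
        start = 0
        while True:
            p = sub.find(U_RICH_SEED, start)
            if p < 0:
                break
            motifs.append(("U_RICH", iv.start + p, len(U_RICH_SEED)))
            start = p + len(U_RICH_SEED)
    return seq, exon_ivs, motifs, counts


def _oriented_to_genomic(iv: Interval, gene_start: int, gene_len: int, strand: str) -> Interval:
    if strand == "+":
        return Interval(gene_start + iv.start, gene_start + iv.end)
    return Interval(gene_start + gene_len - iv.end, gene_start + gene_len - iv.start)


def _plan_cds(exons_or, gene_start, gene_len, strand) -> Interval:
    first, last = exons_or[0], exons_or[-1]
    cds_or = Interval(
        first.start + int(0.4 * len(first)), last.end - int(0.5 * len(last))
    )
    g = _oriented_to_genomic(cds_or, gene_start, gene_len, strand)
    return g


def _plan_event(rng, config: SimConfig, gene: GeneModel, t: Transcript, etype: str) -> dict:
    """Choose coordinates and PSI levels for one planted event."""
    exons = t.exons
    nx = len(exons)
    direction = 1.0 if rng.random() < 0.5 else -1.0
    psi_c = config.base_psi - direction * config.delta_psi / 2
    psi_t = config.base_psi + direction * config.delta_psi / 2
    row = dict(
        gene_id=gene.gene_id, type=etype, strand=gene.strand,
        psi_control=psi_c, psi_treated=psi_t, ir_fraction=np.nan,
        exon_lo=-1, exon_hi=-1, alt_l=-1, alt_r=-1,
        intron_start=-1, intron_end=-1,
    )
    if etype == sp.INTRON_R:
        k = int(rng.integers(0, nx - 1))
        iv = t.introns[k]
        row.update(ir_fraction=config.ir_fraction,
                   intron_start=iv.start, intron_end=iv.end,
                   psi_control=np.nan, psi_treated=np.nan)
        return row
    if etype in (sp.ES, sp.CASSETTE):
        run = 1 if etype == sp.ES else 2
        j = int(rng.integers(1, nx - run))
        row.update(exon_lo=j, exon_hi=j + run - 1,
                   alt_l=exons[j - 1].end, alt_r=exons[j + run].start)
        return row
    if etype == sp.MXE:
        i = int(rng.integers(0, nx - 3))
        row.update(exon_lo=i + 1, exon_hi=i + 2)
        return row
    if etype in (sp.A5SS, sp.A3SS):
        j = int(rng.integers(0, nx - 1))  # intron index
        intron = t.introns[j]
        novel_left = (etype == sp.A5SS) == (gene.strand == "+")
        if novel_left:
            row.update(alt_l=intron.start + 30, alt_r=intron.end, exon_lo=j, exon_hi=j + 1)
        else:
            row.update(alt_l=intron.start, alt_r=intron.end - 30, exon_lo=j, exon_hi=j + 1)
        return row
    # alternative first/last exon pairs
    at_left = (etype == sp.MXE5P) == (gene.strand == "+")
    if at_left:
        row.update(exon_lo=0, exon_hi=1,
                   alt_l=exons[0].end, alt_r=exons[2].start)
    else:
        row.update(exon_lo=nx - 2, exon_hi=nx - 1,
                   alt_l=exons[nx - 3].end, alt_r=exons[nx - 1].start)
    return row


def _plan_binding(config: SimConfig, models: Sequence[GeneModel], truth: SimTruth) -> None:
    """Assign bound genes, CLIP signal (increasing in motif count), affinity
    tiers, tier-dependent destabilization, and ChIP promoter placements."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = truth.genes
    n = len(genes)
    eligible = genes["motifs_total"].to_numpy() > 0
    as_mask = (genes["event_type"] != "none").to_numpy()
    n_bound = int(round(config.frac_bound * n))
    bound = np.zeros(n, dtype=bool)
    # bind the stated fraction of AS genes first, then fill from the rest
    as_idx = np.flatnonzero(as_mask & eligible)
    k_as = min(int(round(config.frac_as_bound * len(as_idx))), n_bound)
    chosen = rng.choice(as_idx, size=k_as, replace=False) if k_as else np.array([], int)
    bound[chosen] = True
    rest = np.flatnonzero(eligible & ~bound)
    k_rest = min(n_bound - bound.sum(), len(rest))
    if k_rest > 0:
        bound[rng.choice(rest, size=int(k_rest), replace=False)] = True
    genes["bound"] = bound

    noise = np.exp(rng.normal(0.0, config.clip_noise_sd, n))
    signal = np.where(
        bound, config.clip_signal_scale * genes["motifs_total"].to_numpy() * noise, 0.0
    )
    genes["clip_signal_planted"] = signal
    # expected control FPKM (up to the common library factor): junction reads
    # per gene over exonic length
    expected_counts = (
        genes["n_junctions"].to_numpy() * config.mean_depth * genes["depth_factor"].to_numpy()
    )
    fpkm_proxy = expected_counts / genes["exonic_length"].to_numpy()
    genes["clip_affinity_planted"] = np.where(bound, signal / fpkm_proxy, 0.0)
    tiers = np.array(["unbound"] * n, dtype=object)
    vals = genes.loc[bound, "clip_affinity_planted"].to_numpy()
    if bound.sum() >= 3:
        q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
        tiers[bound] = np.where(vals <= q1, "weak", np.where(vals <= q2, "median", "strong"))
    genes["tier"] = tiers
    effect = pd.Series(dict(config.affinity_effect)).reindex(
        pd.Index(tiers)
    ).fillna(0.0).to_numpy()
    genes["log2fc_tier"] = effect
    genes["log2fc_total"] = genes["log2fc_de"] + genes["log2fc_tier"]

    chip = np.zeros(n, dtype=bool)
    k_chip = int(round(config.frac_chip * n))
    if k_chip:
        chip[rng.choice(n, size=k_chip, replace=False)] = True
    genes["chip_bound"] = chip
    chip_rows = []
    for gi, gene in enumerate(models):
        tss = gene.tss
        sgn = 1 if gene.strand == "+" else -1
        if chip[gi]:
            k = int(rng.integers(config.chip_peaks_per_gene[0],
                                 config.chip_peaks_per_gene[1] + 1))
            for pk in range(k):
                offset = int(rng.integers(-2000, 1000))
                center = max(100, tss + sgn * offset)  # keep peaks on-chromosome
                fe = float(rng.uniform(*config.chip_fold_enrichment))
                chip_rows.append(dict(
                    chrom=gene.chrom, start=center - 100, end=center + 100,
                    name=f"chip_{gene.gene_id}_{pk}", fold_enrichment=round(fe, 2),
                    strand=".",
                ))
        elif rng.random() < config.frac_chip_distal:
            center = max(100, tss + sgn * 20_000)
            fe = float(rng.uniform(*config.chip_fold_enrichment))
            chip_rows.append(dict(
                chrom=gene.chrom, start=center - 100, end=center + 100,
                name=f"chip_{gene.gene_id}_distal", fold_enrichment=round(fe, 2),
                strand=".",
            ))
    chip_peaks = pd.DataFrame(
        chip_rows,
        columns=["chrom", "start", "end", "name", "fold_enrichment", "strand"],
    )
    genes.attrs["chip_peaks"] = chip_peaks
    # the truth promoter score applies the same window rule naively per gene
    # (windows of neighboring genes may overlap, so placement alone is not a
    # score); this loop doubles as a brute-force oracle
    scores = np.zeros(n)
    for gi, gene in enumerate(models):
        if gene.strand == "+":
            w0, w1 = gene.tss - 10_000, gene.tss + 3_000
        else:
            w0, w1 = gene.tss - 3_000, gene.tss + 10_000
        for r in chip_peaks.itertuples(index=False):
            if r.chrom == gene.chrom and r.start < w1 and w0 < r.end:
                scores[gi] += r.fold_enrichment
    genes["chip_score_planted"] = scores


# ---------------------------------------------------------------------------
# Counts and coverage
# ---------------------------------------------------------------------------

def _junction_rates(t: Transcript, event: Optional[pd.Series]) -> dict:
    """Per-junction usage multipliers (control, treated) relative to gene depth."""
    rates = {j: [1.0, 1.0] for j in t.junctions()}
    if event is None:
        return rates
    etype = event["type"]
    exons = t.exons
    psi = (float(event["psi_control"]), float(event["psi_treated"]))
    if etype == sp.INTRON_R:
        j = (int(event["intron_start"]), int(event["intron_end"]))
        rates[j] = [1.0, 1.0 - float(event["ir_fraction"])]
        return rates

    def jn(i, j):
        return (exons[i].end, exons[j].start)

    lo, hi = int(event["exon_lo"]), int(event["exon_hi"])
    if etype in (sp.ES, sp.CASSETTE):
        for k in range(lo - 1, hi + 1):
            rates[jn(k, k + 1)] = list(psi)
        rates[(int(event["alt_l"]), int(event["alt_r"]))] = [1 - psi[0], 1 - psi[1]]
    elif etype == sp.MXE:
        i = lo - 1  # flanking upstream exon
        rates[jn(i, lo)] = list(psi)
        rates[(exons[lo].end, exons[hi + 1].start)] = list(psi)
        rates[(exons[i].end, exons[hi].start)] = [1 - psi[0], 1 - psi[1]]
        rates[jn(hi, hi + 1)] = [1 - psi[0], 1 - psi[1]]
        rates[jn(lo, hi)] = [0.0, 0.0]
    elif etype in (sp.A5SS, sp.A3SS):
        rates[jn(lo, hi)] = list(psi)
        rates[(int(event["alt_l"]), int(event["alt_r"]))] = [1 - psi[0], 1 - psi[1]]
    else:  # 5pMXE / 3pMXE
        alt = (int(event["alt_l"]), int(event["alt_r"]))
        if lo == 0:
            rates[jn(0, 1)] = [0.0, 0.0]
            rates[jn(1, 2)] = list(psi)
        else:
            rates[jn(lo, hi)] = [0.0, 0.0]
            rates[jn(lo - 1, lo)] = list(psi)
        rates[alt] = [1 - psi[0], 1 - psi[1]]
    return rates


def _exon_rates(t: Transcript, event: Optional[pd.Series]) -> dict:
    rates = {i: [1.0, 1.0] for i in range(len(t.exons))}
    if event is None:
        return rates
    etype = event["type"]
    if etype in (sp.ES, sp.CASSETTE, sp.MXE5P, sp.MXE3P):
        psi = (float(event["psi_control"]), float(event["psi_treated"]))
        for k in range(int(event["exon_lo"]), int(event["exon_hi"]) + 1):
            rates[k] = list(psi)
    elif etype == sp.MXE:
        psi = (float(event["psi_control"]), float(event["psi_treated"]))
        rates[int(event["exon_lo"])] = list(psi)
        rates[int(event["exon_hi"])] = [1 - psi[0], 1 - psi[1]]
    return rates


def _draw(rng: np.random.Generator, lam, phi: float):
    lam = np.asarray(lam, dtype=float)
    if phi > 0:
        shape = 1.0 / phi
        lam = rng.gamma(shape, lam * phi)
    return rng.poisson(lam)


def simulate_counts(
    config: SimConfig,
    models: Sequence[GeneModel],
    truth: SimTruth,
    emit_coverage: bool = True,
) -> tuple[pd.DataFrame, dict[str, CoverageTrack], pd.DataFrame]:
    """Draw per-sample junction tables, coverage tracks, and gene counts."""
    config.validate()
    if config.mean_depth <= 0:
        raise ValueError("zero depth")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    events_by_gene = (
        {r["gene_id"]: r for _, r in truth.events.iterrows()}
        if len(truth.events)
        else {}
    )
    samples = [
        (cond, f"{cond}_{i + 1}")
        for cond in ("control", "treated")
        for i in range(config.n_replicates)
    ]
    chrom_sizes = {}
    for g in models:
        chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.span.end + 300)

    junc_rows = []
    counts_mat = {}
    tracks: dict[str, CoverageTrack] = {}
    for cond, sample in samples:
        ci = 0 if cond == "control" else 1
        arrays = (
            {c: np.zeros(nbase) for c, nbase in chrom_sizes.items()}
            if emit_coverage
            else None
        )
        gene_counts = {}
        for gene in models:
            t = gene.primary_transcript
            info = truth.genes.loc[gene.gene_id]
            d = config.mean_depth * float(info["depth_factor"])
            if ci == 1:
                d *= 2.0 ** float(info["log2fc_total"])
            event = events_by_gene.get(gene.gene_id)
            jr = _junction_rates(t, event)
            total = 0
            for (l, r), mult in jr.items():
                lam = d * mult[ci]
                cnt = int(_draw(rng, lam, config.overdispersion)) if lam > 0 else 0
                total += cnt
                if cnt > 0:
                    junc_rows.append(
                        dict(chrom=gene.chrom, donor_end=l, acceptor_start=r,
                             strand=gene.strand, count=cnt, sample=sample)
                    )
            gene_counts[gene.gene_id] = total
            if arrays is not None:
                arr = arrays[gene.chrom]
                er = _exon_rates(t, event)
                for k, e in enumerate(t.exons):
                    lam = d * er[k][ci]
                    arr[e.start : e.end] = _draw(rng, np.full(len(e), lam),
                                                 config.overdispersion)
                ir_iv = None
                ir_level = 0.0
                if event is not None and event["type"] == sp.INTRON_R and ci == 1:
                    ir_iv = (int(event["intron_start"]), int(event["intron_end"]))
                    ir_level = float(event["ir_fraction"]) * d
                for iv in t.introns:
                    lam = config.intron_background * d
                    if ir_iv is not None and (iv.start, iv.end) == ir_iv:
                        lam = ir_level
                    arr[iv.start : iv.end] = _draw(rng, np.full(len(iv), lam),
                                                   config.overdispersion)
        counts_mat[sample] = gene_counts
        if arrays is not None:
            tracks[sample] = CoverageTrack(arrays)

    junctions = pd.DataFrame(
        junc_rows,
        columns=["chrom", "donor_end", "acceptor_start", "strand", "count", "sample"],
    )
    gene_counts_df = pd.DataFrame(counts_mat)
    gene_counts_df.index.name = "gene_id"
    return junctions, tracks, gene_counts_df


# ---------------------------------------------------------------------------
# Binding data
# ---------------------------------------------------------------------------

def simulate_binding(
    config: SimConfig, models: Sequence[GeneModel], truth: SimTruth
) -> BindingData:
    """Materialize CLIP peaks (centered on planted motifs), the per-gene CLIP
    signal, a CLIP coverage proxy, and the ChIP peak table."""
    genes = truth.genes
    bad = genes.index[(genes["bound"]) & (genes["motifs_total"] == 0)]
    if len(bad):
        raise ValueError(f"bound gene(s) without motifs: {list(bad[:3])}")
    model_by_id = {g.gene_id: g for g in models}
    chrom_sizes = {}
    for g in models:
        chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.span.end + 300)
    clip_arrays = {c: np.zeros(nb) for c, nb in chrom_sizes.items()}
    rows = []
    hw = config.peak_halfwidth
    for gene_id, minfo in truth.motifs.groupby("gene_id", sort=True):
        if not genes.loc[gene_id, "bound"]:
            continue
        gene = model_by_id[gene_id]
        fe = max(genes.loc[gene_id, "clip_signal_planted"], 1.0) / max(
            genes.loc[gene_id, "motifs_total"], 1
        )
        for i, r in enumerate(minfo.sort_values(["start", "pattern"]).itertuples()):
            start = max(gene.span.start, r.start - hw)
            end = min(gene.span.end, r.end + hw)
            rows.append(dict(chrom=r.chrom, start=start, end=end,
                             name=f"clip_{gene_id}_{i}",
                             fold_enrichment=round(float(fe), 2), strand=gene.strand))
            clip_arrays[r.chrom][start:end] += fe
    clip_peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "fold_enrichment", "strand"]
    )
    clip_signal = genes["clip_signal_planted"].rename("clip_signal")
    chip_peaks = genes.attrs["chip_peaks"]
    return BindingData(
        clip_peaks=clip_peaks,
        clip_signal=clip_signal,
        chip_peaks=chip_peaks,
        clip_track=CoverageTrack(clip_arrays),
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig, emit_coverage: bool = True) -> SimData:
    genome, models, truth = simulate_reference(config)
    junctions, coverage, gene_counts = simulate_counts(
        config, models, truth, emit_coverage=emit_coverage
    )
    binding = simulate_binding(config, models, truth)
    return SimData(
        config=config, genome=genome, models=models, truth=truth,
        junctions=junctions, coverage=coverage, gene_counts=gene_counts,
        binding=binding,
    )


def write_simulation(data: SimData, outdir: str | Path) -> None:
    """Write the complete dataset in the standard dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(data.genome, outdir / "genome.fa")
    write_annotation(data.models, outdir / "annotation.gtf")
    write_junctions(data.junctions, outdir / "junctions.tsv")
    write_gene_counts(data.gene_counts, outdir / "gene_counts.tsv")
    for sample, track in data.coverage.items():
        track.to_bedgraph(outdir / f"coverage_{sample}.bedgraph")
    write_peaks(data.binding.clip_peaks, outdir / "clip_peaks.bed")
    write_peaks(data.binding.chip_peaks, outdir / "chip_peaks.bed")
    data.binding.clip_signal.to_csv(outdir / "clip_signal.tsv", sep="\t",
                                    index_label="gene_id")
    data.binding.clip_track.to_bedgraph(outdir / "clip_coverage.bedgraph")
    data.truth.to_dir(outdir / "truth")
    cfg = dataclasses.asdict(data.config)
    cfg["affinity_effect"] = dict(cfg["affinity_effect"])
    cfg["motif_seeding"] = dict(cfg["motif_seeding"])
    pd.Series(cfg, dtype=object).to_json(outdir / "sim_config.json", indent=2)
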