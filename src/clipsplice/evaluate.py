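"""Recovery of planted truth by the analysis stages.

These helpers compare analysis outputs against a :class:`SimTruth` table:
how many planted junction events were detected with the correct type and
flagged significant, how sensitive/specific the intron-retention caller
was, how well IR intensities and binding tiers were recovered. They are the
quantitative bridge between the simulator's ground truth and the pipeline.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import splicing as sp
from .simulate import SimData
from .splicing import ASEvent


def match_planted_junction_events(
    truth_events: pd.DataFrame, detected: Sequence[ASEvent]
) -> pd.DataFrame:
    """One row per planted junction-based event with its detection status.

    A planted event is recovered when a detected event in the same gene has
    the same type and (where the plant records one) the same alternative
    junction.
    """
    by_gene: dict[str, list[ASEvent]] = {}
    for ev in detected:
        by_gene.setdefault(ev.gene_id, []).append(ev)
    rows = []
    planted = truth_events[truth_events["type"] != sp.INTRON_R]
    for r in planted.itertuples(index=False):
        match = None
        for ev in by_gene.get(r.gene_id, []):
            if ev.etype != r.type:
                continue
            if r.alt_l >= 0 and (int(r.alt_l), int(r.alt_r)) not in ev.alt_junctions:
                continue
            match = ev
            break
        rows.append(
            dict(gene_id=r.gene_id, type=r.type, detected=match is not None,
                 event_id=match.event_id if match else "")
        )
    return pd.DataFrame(rows)


def junction_event_recovery(data: SimData, rase: pd.DataFrame,
                            detected: Sequence[ASEvent]) -> dict[str, float]:
    """Detection and significance rates over planted junction-based events."""
    matches = match_planted_junction_events(data.truth.events, detected)
    if matches.empty:
        return {"n_planted": 0, "detection_rate": float("nan"),
                "significant_rate": float("nan")}
    sig = rase.set_index("event_id")["significant"]
    matched = matches[matches["detected"]]
    n_sig = int(sig.reindex(matched["event_id"]).fillna(False).sum())
    return {
        "n_planted": int(len(matches)),
        "detection_rate": float(matches["detected"].mean()),
        "significant_rate": n_sig / len(matches),
    }


def ir_recovery(data: SimData, ir_events: Sequence[ASEvent],
                rase: pd.DataFrame) -> dict[str, float]:
    """Sensitivity on planted retained introns, false-call rate among null
    introns, and the largest |estimated - planted| IR intensity error."""
    truth = data.truth.events
    planted = truth[truth["type"] == sp.INTRON_R]
    planted_keys = {
        (r.gene_id, int(r.intron_start), int(r.intron_end))
        for r in planted.itertuples(index=False)
    }
    called_keys = {
        (e.gene_id, e.intron.start, e.intron.end) for e in ir_events
    }
    n_hit = len(planted_keys & called_keys)

    ir_gene_ids = set(planted["gene_id"])
    n_null_introns = sum(
        len(g.primary_transcript.introns)
        for g in data.models
        if g.gene_id not in ir_gene_ids
    )
    false_calls = sum(1 for k in called_keys if k not in planted_keys)

    errors = []
    if not rase.empty:
        ir_rows = rase[rase["type"] == sp.INTRON_R].set_index("gene_id")
        for r in planted.itertuples(index=False):
            if r.gene_id in ir_rows.index:
                est = float(ir_rows.loc[r.gene_id, "ir_intensity_treated"])
                errors.append(abs(est - float(r.ir_fraction)))
    return {
        "n_planted_ir": int(len(planted_keys)),
        "ir_sensitivity": n_hit / len(planted_keys) if planted_keys else float("nan"),
        "ir_false_call_rate": false_calls / n_null_introns if n_null_introns else 0.0,
        "ir_intensity_max_abs_error": float(max(errors)) if errors else float("nan"),
    }


def tier_rank_recovery(data: SimData, affinity: pd.DataFrame) -> float:
    """Spearman correlation between recovered CLIP affinity and planted tier."""
    order = {"weak": 1, "median": 2, "strong": 3}
    truth = data.truth.genes
    bound = truth.index[truth["tier"].isin(order)]
    common = bound.intersection(affinity.index)
    ranks = truth.loc[common, "tier"].map(order)
    vals = affinity.loc[common, "clip_affinity"]
    return float(stats.spearmanr(ranks, vals).statistic)


def tier_effect_trial(
    seed: int,
    effects: dict[str, float] | None = None,
    sigma: float = 0.3,
    n_per_tier: int = 300,
) -> tuple[bool, float, float]:
    """One tier-proportional destabilization trial.

    Draws Gaussian log2 fold-change responses per tier (defaults: strong
    +0.5, median +0.25, weak 0, sigma 0.3, n=300/tier), runs the ECDF shift
    analysis, and reports whether the recovered tier-median ordering matches
    the planted one, the strong-vs-weak Tukey p, and the strong-vs-weak KS p.
    """
    from .affinity import ecdf_shift_analysis

    effects = effects or {"strong": 0.5, "median": 0.25, "weak": 0.0}
    rng = np.random.default_rng(seed)
    genes, tiers, resp = [], [], []
    for tier in ("strong", "median", "weak"):
        for i in range(n_per_tier):
            genes.append(f"{tier}_{i}")
            tiers.append(tier)
            resp.append(rng.normal(effects[tier], sigma))
    tiered = pd.DataFrame({"clip_tier": tiers}, index=genes)
    response = pd.Series(resp, index=genes)
    cmp_ = ecdf_shift_analysis(tiered, response)
    ordering = (
        cmp_.medians["strong"] > cmp_.medians["median"] > cmp_.medians["weak"]
    )
    p_sw = tukey_pair_p(cmp_.tukey, "strong", "weak")
    return ordering, p_sw, cmp_.ks_p


def null_ks_trial(seed: int, sigma: float = 0.3, n_per_tier: int = 300) -> float:
    """Strong-vs-weak KS p for one null draw (no planted tier effect)."""
    import warnings

    from .affinity import ecdf_shift_analysis

    rng = np.random.default_rng(seed)
    genes = [f"g{j}" for j in range(2 * n_per_tier)]
    tiers = ["strong"] * n_per_tier + ["weak"] * n_per_tier
    tiered = pd.DataFrame({"clip_tier": tiers}, index=genes)
    response = pd.Series(rng.normal(0.0, sigma, 2 * n_per_tier), index=genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp_ = ecdf_shift_analysis(tiered, response, pairwise=False)
    return cmp_.ks_p


def tukey_pair_p(tukey: pd.DataFrame, a: str, b: str) -> float:
    """Adjusted p-value for one pair from a Tukey HSD summary table."""
    for r in tukey.itertuples(index=False):
        if {str(r.group1), str(r.group2)} == {a, b}:
            return float(getattr(r, "_3"))  # 'p-adj' column
    raise KeyError(f"pair ({a}, {b}) not in Tukey table")


def bound_rasg_fraction(data: SimData, rase: pd.DataFrame) -> float:
    """Fraction of significant differential-splicing genes carrying CLIP peaks."""
    rasg = set(rase.loc[rase["significant"], "gene_id"])
    if not rasg:
        return float("nan")
    bound = set(data.truth.genes.index[data.truth.genes["bound"]])
    return len(rasg & bound) / len(rasg)
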