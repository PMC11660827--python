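"""Rescue ("drug-sensitivity") classification of genes in a three-group design.

Two strategies identify genes dysregulated by disease and normalized by the
drug:

Strategy A (consensus-DE based): the gene is a consensus DEG with
|log2FC| >= 1 in control vs disease, and is *not* a consensus DEG with
|log2FC| <= 1 in control vs disease+drug.

Strategy B (five sequential FPM/CI rules):
  R1  at least one group's mean abundance is > 3 FPM (strict);
  R2  |log2FC(control -> disease)| > 1 (strict);
  R3  the 95% CIs of control and disease do NOT overlap;
  R4  the 95% CIs of disease and disease+drug do NOT overlap;
  R5  the 95% CIs of control and disease+drug DO overlap.

Note the deliberate asymmetry in the fold-change gates: Strategy B uses
strict > 1 while Strategy A uses >= 1 — each follows its own stated rule.

Confidence intervals default to t-intervals on log2(FPM + 1), back-
transformed; a linear-scale mode is available for sensitivity analysis.
Touching interval endpoints count as overlap (conservative: it is harder to
establish separation in R3/R4 and easier to establish restoration in R5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from txrescue.counts import AbundanceMatrix
from txrescue.de import DEResult, log2_fold_change

Scale = Literal["log2p1", "linear"]

RULE_NAMES = ("r1_abundance", "r2_lfc", "r3_ctrl_dis_disjoint",
              "r4_dis_drug_disjoint", "r5_ctrl_drug_overlap")


@dataclass
class GroupInterval:
    """Confidence interval for one group's mean abundance."""

    group: str
    n: int
    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    scale: Scale = "log2p1"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("confidence interval undefined for n < 2")
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("interval must bracket its estimate")


@dataclass
class RescueCall:
    """Per-gene classification record."""

    gene_id: str
    direction_disease: Literal["up", "down", "none"]
    strategy_a_sensitive: bool
    strategy_b_sensitive: bool
    rules_passed: tuple[bool, bool, bool, bool, bool]
    log2fc_disease: float = float("nan")


@dataclass
class StrategySummary:
    """Fig.-2B-style bookkeeping of directions x sensitivity, per strategy."""

    n_genes: int
    n_regulated: int
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float
    cells: pd.DataFrame  # direction x strategy: counts, pct of direction, mean lfc
    jaccard_ab: float
    overlap_a_in_b: float  # |A ∩ B| / |B|

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_regulated": self.n_regulated,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "pct_up": self.pct_up,
            "pct_down": self.pct_down,
            "jaccard_ab": self.jaccard_ab,
            "overlap_a_in_b": self.overlap_a_in_b,
            "cells": self.cells.to_dict(orient="records"),
        }


def group_ci(
    values: Sequence[float] | np.ndarray,
    level: float = 0.95,
    scale: Scale = "log2p1",
    group: str = "",
) -> GroupInterval:
    """t-based confidence interval for a group's mean abundance.

    Default scale ``log2p1``: the interval is computed as
    mean ± t_{1-(1-level)/2, n-1} * sd / sqrt(n) on log2(x + 1) and the
    endpoints are back-transformed by 2^y - 1.  ``linear`` computes the same
    interval on the raw values.  Zero spread yields a point interval.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("confidence interval needs >= 2 values")
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    y = np.log2(x + 1.0) if scale == "log2p1" else x
    n = len(y)
    m = y.mean()
    sd = y.std(ddof=1)
    half = stats.t.ppf(1 - (1 - level) / 2, n - 1) * sd / np.sqrt(n)
    lo, hi = m - half, m + half
    if scale == "log2p1":
        est, lo, hi = 2.0**m - 1.0, 2.0**lo - 1.0, 2.0**hi - 1.0
    else:
        est = m
    return GroupInterval(group=group, n=n, estimate=float(est),
                         lower=float(lo), upper=float(hi),
                         level=level, scale=scale)


def intervals_overlap(a: GroupInterval, b: GroupInterval) -> bool:
    """Closed-interval overlap test; touching endpoints overlap."""
    if a.scale != b.scale:
        raise ValueError(f"mismatched interval scales: {a.scale} vs {b.scale}")
    return a.lower <= b.upper and b.lower <= a.upper


def classify_strategy_a(
    gene_id: str,
    de_control_disease: DEResult,
    de_control_drug: DEResult,
    lfc_threshold: float = 1.0,
) -> bool:
    """DE-based "normalized" criterion for one gene.

    True iff the gene is a consensus DEG with |log2FC| >= threshold in
    control vs disease, AND is not a consensus DEG with |log2FC| <= threshold
    in control vs disease+drug.
    """
    for de in (de_control_disease, de_control_drug):
        if gene_id not in set(de.table["gene_id"]):
            raise KeyError(f"gene {gene_id!r} missing from comparison {de.comparison}")
    cd = de_control_disease.table.set_index("gene_id").loc[gene_id]
    ce = de_control_drug.table.set_index("gene_id").loc[gene_id]
    dysregulated = bool(cd["consensus_deg"]) and abs(cd["log2fc"]) >= lfc_threshold
    normalized = (not bool(ce["consensus_deg"])) and abs(ce["log2fc"]) <= lfc_threshold
    return dysregulated and normalized


def classify_strategy_b(
    gene_id: str,
    control: Sequence[float],
    disease: Sequence[float],
    drug: Sequence[float],
    fpm_min: float = 3.0,
    lfc_min: float = 1.0,
    ci_level: float = 0.95,
    scale: Scale = "log2p1",
    pseudocount: float = 1.0,
) -> RescueCall:
    """Five-rule FPM/CI classification of one gene (see module docstring)."""
    groups = {"control": np.asarray(control, float),
              "disease": np.asarray(disease, float),
              "disease_drug": np.asarray(drug, float)}
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs >= 2 samples")

    means = {g: float(v.mean()) for g, v in groups.items()}
    lfc = log2_fold_change(means["control"], means["disease"], pseudocount)

    r1 = max(means.values()) > fpm_min
    r2 = abs(lfc) > lfc_min
    ci = {g: group_ci(v, ci_level, scale, group=g) for g, v in groups.items()}
    r3 = not intervals_overlap(ci["control"], ci["disease"])
    r4 = not intervals_overlap(ci["disease"], ci["disease_drug"])
    r5 = intervals_overlap(ci["control"], ci["disease_drug"])

    rules = (r1, r2, r3, r4, r5)
    direction = ("up" if lfc > 0 else "down") if r2 else "none"
    return RescueCall(
        gene_id=gene_id,
        direction_disease=direction,
        strategy_a_sensitive=False,
        strategy_b_sensitive=all(rules),
        rules_passed=rules,
        log2fc_disease=float(lfc),
    )


def _group_ci_bounds(
    x: np.ndarray, level: float, scale: Scale
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized CI bounds for a genes x samples block of one group."""
    y = np.log2(x + 1.0) if scale == "log2p1" else x
    n = y.shape[1]
    m = y.mean(axis=1)
    sd = y.std(axis=1, ddof=1)
    half = stats.t.ppf(1 - (1 - level) / 2, n - 1) * sd / np.sqrt(n)
    lo, hi = m - half, m + half
    if scale == "log2p1":
        lo, hi = 2.0**lo - 1.0, 2.0**hi - 1.0
    return lo, hi


def classify_study(
    am: AbundanceMatrix,
    de_control_disease: DEResult,
    de_control_drug: DEResult,
    fpm_min: float = 3.0,
    lfc_min_b: float = 1.0,
    lfc_min_a: float = 1.0,
    ci_level: float = 0.95,
    scale: Scale = "log2p1",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Classify every gene by both strategies (vectorized over genes).

    Returns a table with one row per gene: direction, the five Strategy B
    rule outcomes, both sensitivity flags and the two fold changes.  The
    reported direction is the Strategy A ("cirrhosis-sensitive") one —
    consensus DEG with |log2FC| >= ``lfc_min_a`` in control vs disease —
    falling back to ``none`` for unregulated genes.
    """
    for name in ("control", "disease", "disease_drug"):
        if len(am.group_indices(name)) < 2:
            raise ValueError(f"group {name!r} needs >= 2 samples")
    xc = am.fpm[:, am.group_indices("control")]
    xd = am.fpm[:, am.group_indices("disease")]
    xe = am.fpm[:, am.group_indices("disease_drug")]

    mc, md, me = xc.mean(axis=1), xd.mean(axis=1), xe.mean(axis=1)
    lfc_b = log2_fold_change(mc, md, pseudocount)

    r1 = np.maximum(np.maximum(mc, md), me) > fpm_min
    r2 = np.abs(lfc_b) > lfc_min_b
    lo_c, hi_c = _group_ci_bounds(xc, ci_level, scale)
    lo_d, hi_d = _group_ci_bounds(xd, ci_level, scale)
    lo_e, hi_e = _group_ci_bounds(xe, ci_level, scale)
    r3 = ~((lo_c <= hi_d) & (lo_d <= hi_c))
    r4 = ~((lo_d <= hi_e) & (lo_e <= hi_d))
    r5 = (lo_c <= hi_e) & (lo_e <= hi_c)
    strategy_b = r1 & r2 & r3 & r4 & r5

    cd = de_control_disease.table.set_index("gene_id").loc[am.gene_ids]
    ce = de_control_drug.table.set_index("gene_id").loc[am.gene_ids]
    lfc_cd = cd["log2fc"].to_numpy()
    lfc_ce = ce["log2fc"].to_numpy()
    regulated = cd["consensus_deg"].to_numpy() & (np.abs(lfc_cd) >= lfc_min_a)
    normalized = ~ce["consensus_deg"].to_numpy() & (np.abs(lfc_ce) <= lfc_min_a)
    strategy_a = regulated & normalized

    direction = np.where(regulated, np.where(lfc_cd > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "gene_id": am.gene_ids,
            "direction": direction,
            "r1_abundance": r1,
            "r2_lfc": r2,
            "r3_ctrl_dis_disjoint": r3,
            "r4_dis_drug_disjoint": r4,
            "r5_ctrl_drug_overlap": r5,
            "strategy_a": strategy_a,
            "strategy_b": strategy_b,
            "log2fc_control_disease": lfc_cd,
            "log2fc_control_drug": lfc_ce,
            "log2fc_fpm_b": lfc_b,
        }
    )


def summarize_strategies(calls: pd.DataFrame) -> StrategySummary:
    """Bookkeeping of regulated genes by direction and drug sensitivity.

    Expects the table produced by :func:`classify_study` (columns
    ``direction``, ``strategy_a``, ``strategy_b``,
    ``log2fc_control_disease``, ``log2fc_control_drug``).  Percentages are
    relative to the regulated genes of the same direction.
    """
    if calls.empty:
        raise ValueError("empty call table")
    regulated = calls[calls["direction"].isin(["up", "down"])]
    n_reg = len(regulated)
    n_up = int((regulated["direction"] == "up").sum())
    n_down = n_reg - n_up

    rows = []
    for direction in ("up", "down"):
        sub = regulated[regulated["direction"] == direction]
        for strategy in ("strategy_a", "strategy_b"):
            for sensitive in (True, False):
                cell = sub[sub[strategy] == sensitive]
                rows.append(
                    {
                        "direction": direction,
                        "strategy": strategy.removeprefix("strategy_").upper(),
                        "sensitive": sensitive,
                        "n": len(cell),
                        "pct_of_direction": 100.0 * len(cell) / len(sub) if len(sub) else 0.0,
                        "mean_log2fc_control_disease": float(
                            cell["log2fc_control_disease"].mean()
                        ) if len(cell) else float("nan"),
                        "mean_log2fc_control_drug": float(
                            cell["log2fc_control_drug"].mean()
                        ) if len(cell) else float("nan"),
                    }
                )
    cells = pd.DataFrame(rows)

    set_a = set(calls.loc[calls["strategy_a"], "gene_id"])
    set_b = set(calls.loc[calls["strategy_b"], "gene_id"])
    union = set_a | set_b
    jac = len(set_a & set_b) / len(union) if union else 0.0
    a_in_b = len(set_a & set_b) / len(set_b) if set_b else 0.0

    return StrategySummary(
        n_genes=len(calls),
        n_regulated=n_reg,
        n_up=n_up,
        n_down=n_down,
        pct_up=100.0 * n_up / n_reg if n_reg else 0.0,
        pct_down=100.0 * n_down / n_reg if n_reg else 0.0,
        cells=cells,
        jaccard_ab=jac,
        overlap_a_in_b=a_in_b,
    )
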