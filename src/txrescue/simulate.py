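"""Synthetic three-group count studies and assay traces with known truth.

The count generator emulates the study design it is meant to test: three
groups (control / disease / disease+drug) of sizes 4/5/5, a few thousand
genes with log-normal baseline abundances, negative-binomial counts
(variance = mu + dispersion * mu^2), and planted gene classes::

    null            no effect in any group
    up_persistent   disease and disease+drug both shifted +effect (log2)
    down_persistent both shifted -effect
    up_rescued      disease shifted +effect, drug group restored
    down_rescued    disease shifted -effect, drug group restored

``rescue_completeness`` interpolates the drug-group mean between disease
(0) and control (1) on the log2 scale.  Library sizes are drawn log-normal
around 2e7 fragments so FPM scaling is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from txrescue.assays import MitoStressTrace
from txrescue.counts import CountMatrix

GENE_CLASSES = ("null", "up_persistent", "down_persistent", "up_rescued", "down_rescued")

_DEFAULT_PROPORTIONS = {
    "null": 0.70,
    "up_persistent": 0.10,
    "down_persistent": 0.10,
    "up_rescued": 0.05,
    "down_rescued": 0.05,
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic three-group count study."""

    n_genes: int = 5000
    group_sizes: tuple[int, int, int] = (4, 5, 5)
    baseline_meanlog: float = float(np.log(100.0))
    baseline_sdlog: float = 1.5
    dispersion: float = 0.05
    dispersion_sdlog: float = 0.0  # optional per-gene log-normal spread
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    effect_log2fc: float = 1.5
    rescue_completeness: float = 1.0
    library_size_mean: float = 2e7
    library_size_sdlog: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("each group needs >= 2 samples")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class: {sorted(unknown)[0]!r}")
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class proportions sum to {total}, not 1")
        if not 0.0 <= self.rescue_completeness <= 1.0:
            raise ValueError("rescue_completeness must lie in [0, 1]")


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of genes to classes."""
    raw = {c: config.class_proportions.get(c, 0.0) * config.n_genes for c in GENE_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    remainders = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in remainders[:short]:
        counts[c] += 1
    return counts


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a synthetic count study; returns (CountMatrix, planted truth).

    The truth table has columns ``gene_id, class, base_abundance`` plus the
    planted log2 group effects ``delta_disease, delta_drug``.  Deterministic
    for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    counts_by_class = _class_counts(config)
    labels = np.repeat(
        [c for c in GENE_CLASSES for _ in range(counts_by_class[c])], 1
    )
    labels = labels[rng.permutation(n)]

    sign = np.zeros(n)
    sign[np.isin(labels, ["up_persistent", "up_rescued"])] = 1.0
    sign[np.isin(labels, ["down_persistent", "down_rescued"])] = -1.0
    delta_disease = sign * config.effect_log2fc
    rescued = np.isin(labels, ["up_rescued", "down_rescued"])
    delta_drug = np.where(
        rescued, (1.0 - config.rescue_completeness) * delta_disease, delta_disease
    )

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=n)
    rel = baseline / baseline.sum()

    sizes = config.group_sizes
    sample_ids = (
        [f"control_{i+1}" for i in range(sizes[0])]
        + [f"disease_{i+1}" for i in range(sizes[1])]
        + [f"drug_{i+1}" for i in range(sizes[2])]
    )
    groups = (["control"] * sizes[0] + ["disease"] * sizes[1]
              + ["disease_drug"] * sizes[2])
    design = dict(zip(sample_ids, groups))

    lib = rng.lognormal(np.log(config.library_size_mean), config.library_size_sdlog,
                        size=len(sample_ids))
    delta_by_group = {
        "control": np.zeros(n),
        "disease": delta_disease,
        "disease_drug": delta_drug,
    }

    if config.dispersion_sdlog > 0:
        disp = config.dispersion * rng.lognormal(0.0, config.dispersion_sdlog, size=n)
    else:
        disp = np.full(n, config.dispersion)

    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j, (sid, grp) in enumerate(zip(sample_ids, groups)):
        mu = rel * lib[j] * 2.0 ** delta_by_group[grp]
        if np.all(disp > 0):
            r = 1.0 / disp
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
        else:
            pois = disp == 0
            r = np.where(pois, 1.0, 1.0 / np.where(pois, 1.0, disp))
            col = rng.negative_binomial(r, r / (r + mu))
            col[pois] = rng.poisson(mu[pois])
            counts[:, j] = col

    gene_ids = [f"gene_{i+1:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": labels,
            "base_abundance": rel,
            "delta_disease": delta_disease,
            "delta_drug": delta_drug,
        }
    )
    cm = CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=counts,
                     design=design)
    return cm, truth


def simulate_mito_trace(
    initial: float,
    min_oligo: float,
    min_rotaa: float,
    fccp: float | None = None,
    cycles_per_phase: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MitoStressTrace:
    """Noisy OCR trace around planted phase plateaus.

    Plateaus must satisfy min_rotaa <= min_oligo <= initial.  Gaussian noise
    (sd ``noise_sd``) is added per cycle and clipped at zero; with zero noise
    the parameter extraction recovers the plateaus exactly.
    """
    if not 0.0 <= min_rotaa <= min_oligo <= initial:
        raise ValueError("plateaus must satisfy 0 <= min_rotaa <= min_oligo <= initial")
    if fccp is None:
        fccp = 1.5 * initial
    rng = np.random.default_rng(seed)
    plateaus = [("basal", initial), ("post_oligomycin", min_oligo),
                ("post_fccp", fccp), ("post_rotenone_antimycin", min_rotaa)]
    phases: list[str] = []
    ocr: list[float] = []
    for phase, level in plateaus:
        for _ in range(cycles_per_phase):
            phases.append(phase)
            ocr.append(max(0.0, level + rng.normal(0.0, noise_sd) if noise_sd > 0 else level))
    return MitoStressTrace(phases=phases, ocr=np.array(ocr))


def recovery_metrics(calls: pd.DataFrame, truth: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Sensitivity / specificity / false-discovery proportion per strategy.

    ``calls`` is the table from :func:`txrescue.rescue.classify_study`;
    ``truth`` the planted table from :func:`simulate_counts`.  A gene counts
    as truly rescued when its planted class is up_rescued or down_rescued.
    """
    if set(calls["gene_id"]) != set(truth["gene_id"]):
        raise ValueError("call table and truth cover different gene universes")
    merged = calls.merge(truth[["gene_id", "class"]], on="gene_id")
    positive = merged["class"].isin(["up_rescued", "down_rescued"]).to_numpy()
    out: dict[str, dict[str, float]] = {}
    for key, col in (("A", "strategy_a"), ("B", "strategy_b")):
        called = merged[col].to_numpy().astype(bool)
        tp = int((called & positive).sum())
        fp = int((called & ~positive).sum())
        fn = int((~called & positive).sum())
        tn = int((~called & ~positive).sum())
        out[key] = {
            "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
            "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
            "fdp": fp / (tp + fp) if (tp + fp) else 0.0,
        }
    return out
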