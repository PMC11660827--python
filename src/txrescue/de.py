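"""Two-caller differential expression with "significant in both" consensus.

The selection criterion is the consensus: a gene is a differentially
expressed gene (DEG) only when its FDR is below alpha in *both* of two
independent callers.  The callers implemented here are deliberately simple,
documented stand-ins sharing nothing but the count matrix:

* :func:`nb_wald_test` — a negative-binomial log-link two-group Wald test
  with per-gene method-of-moments dispersion shrunk 50/50 toward the
  genome-wide median dispersion, and per-sample total-count size factors.
* :func:`logcpm_moderated_t` — a Welch t-test on log2(CPM + 1) with per-group
  gene-wise variances shrunk equal-weight toward their across-gene mean.

Fold changes are raw group-mean FPM ratios with a pseudocount (default 1):
log2FC = log2((mean_b + pc) / (mean_a + pc)), disease relative to control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from txrescue.counts import CountMatrix, normalize_fpm


@dataclass
class DEResult:
    """Per-gene results for one two-group comparison.

    The ``table`` has one row per gene with columns
    ``gene_id, log2fc, p_nb_wald, p_mod_t, fdr_nb_wald, fdr_mod_t,
    consensus_deg, degenerate``.
    """

    comparison: str
    group_a: str
    group_b: str
    alpha: float
    table: pd.DataFrame

    def lfc(self) -> pd.Series:
        return self.table.set_index("gene_id")["log2fc"]

    def consensus(self) -> pd.Series:
        return self.table.set_index("gene_id")["consensus_deg"]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def log2_fold_change(
    mean_a: float | np.ndarray,
    mean_b: float | np.ndarray,
    pseudocount: float = 1.0,
) -> float | np.ndarray:
    """log2((mean_b + pseudocount) / (mean_a + pseudocount)).

    Antisymmetric under swapping the groups; positive means higher in b.
    """
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if np.any(mean_a < 0) or np.any(mean_b < 0):
        raise ValueError("group means must be non-negative")
    out = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    return float(out) if out.ndim == 0 else out


def _size_factors(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("sample with zero total counts")
    return totals / totals.mean()


def _split(cm: CountMatrix, comparison: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    ia = cm.group_indices(comparison[0])
    ib = cm.group_indices(comparison[1])
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(
            f"comparison {comparison} needs >=2 samples per group "
            f"(got {len(ia)} and {len(ib)})"
        )
    return ia, ib


def nb_wald_test(
    cm: CountMatrix, comparison: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial Wald test for a two-group comparison.

    Model: counts[g, j] ~ NB(mean = s_j * q_group(j), variance =
    mu + alpha_g * mu^2) with log link, size factors s_j proportional to the
    per-sample total count.  The per-gene dispersion alpha_g is estimated by
    method of moments on size-factor-normalized counts within each group and
    shrunk 50/50 toward the genome-wide median dispersion.  The Wald statistic
    log(q_b) - log(q_a) over its delta-method standard error is referred to a
    t distribution with 2 * (n_a + n_b - 2) degrees of freedom: at small
    per-group n the normal reference is anticonservative, while the plain
    residual df overcorrects because the equal-weight dispersion shrinkage
    roughly doubles the information in the variance estimate.

    Returns ``(p, degenerate)``: genes with all-zero counts in both groups
    get p = 1 and a degenerate flag.
    """
    ia, ib = _split(cm, comparison)
    counts = cm.counts.astype(float)
    s = _size_factors(counts)
    n_genes = counts.shape[0]

    # method-of-moments dispersion on normalized counts, pooled over groups
    norm = counts / s[None, :]
    alphas = np.full(n_genes, np.nan)
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for idx in (ia, ib):
        y = norm[:, idx]
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        w = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        ok = m > 0
        num[ok] += w * np.clip(a[ok], 0.0, None)
        den[ok] += w
    valid = den > 0
    alphas[valid] = num[valid] / den[valid]
    med = float(np.nanmedian(alphas)) if np.any(valid) else 0.0
    alpha_shrunk = np.where(valid, 0.5 * alphas + 0.5 * med, med)

    sa, sb = s[ia].sum(), s[ib].sum()
    ta = counts[:, ia].sum(axis=1)
    tb = counts[:, ib].sum(axis=1)
    degenerate = (ta == 0) & (tb == 0)

    # continuity correction keeps log(q) finite when one group is all zero
    qa = np.maximum(ta, 0.5) / sa
    qb = np.maximum(tb, 0.5) / sb

    def logvar(q: np.ndarray, idx: np.ndarray, stot: float) -> np.ndarray:
        mu = q[:, None] * s[idx][None, :]
        var_sum = (mu + alpha_shrunk[:, None] * mu**2).sum(axis=1)
        return var_sum / (q * stot) ** 2

    se = np.sqrt(logvar(qa, ia, sa) + logvar(qb, ib, sb))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(qb) - np.log(qa)) / se
    # shrinkage doubles the effective df of the variance estimate
    df = 2 * (len(ia) + len(ib) - 2)
    p = 2.0 * stats.t.sf(np.abs(z), df)
    p = np.where(se == 0, np.where(qa == qb, 1.0, 0.0), p)
    p[degenerate] = 1.0
    return np.clip(p, 0.0, 1.0), degenerate


def logcpm_moderated_t(
    cm: CountMatrix, comparison: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Welch t-test on log2(CPM + 1) with equal-weight variance shrinkage.

    Per-group gene-wise variances are shrunk 50/50 toward the across-gene
    mean variance of that group, then combined in a Welch statistic.  The
    Satterthwaite degrees of freedom are doubled: equal-weight shrinkage
    toward a prior estimated from thousands of genes contributes about as
    much information as the residual variance itself (a prior-df argument in
    the spirit of empirical-Bayes moderated t statistics).  Genes with zero
    (shrunk) variance and zero difference get p = 1 by convention; all-zero
    genes are flagged.
    """
    ia, ib = _split(cm, comparison)
    counts = cm.counts.astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("sample with zero total counts")
    logcpm = np.log2(counts / totals[None, :] * 1e6 + 1.0)

    ya, yb = logcpm[:, ia], logcpm[:, ib]
    na, nb = ya.shape[1], yb.shape[1]
    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    va = ya.var(axis=1, ddof=1)
    vb = yb.var(axis=1, ddof=1)
    va = 0.5 * va + 0.5 * va.mean()
    vb = 0.5 * vb + 0.5 * vb.mean()

    se2 = va / na + vb / nb
    diff = mb - ma
    degenerate = (counts[:, ia].sum(axis=1) == 0) & (counts[:, ib].sum(axis=1) == 0)
    p = np.ones(counts.shape[0])
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff[ok] / np.sqrt(se2[ok])
        df = 2.0 * se2[ok] ** 2 / (
            (va[ok] / na) ** 2 / (na - 1) + (vb[ok] / nb) ** 2 / (nb - 1)
        )
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
    # zero spread, nonzero difference: evidence is unbounded
    p[~ok & (diff != 0)] = 0.0
    p[degenerate] = 1.0
    return np.clip(p, 0.0, 1.0), degenerate


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consensus_deg(
    fdr1: np.ndarray, fdr2: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """True where both callers' FDR is strictly below alpha."""
    fdr1 = np.asarray(fdr1, dtype=float)
    fdr2 = np.asarray(fdr2, dtype=float)
    if fdr1.shape != fdr2.shape:
        raise ValueError("FDR vectors cover different gene universes")
    return (fdr1 < alpha) & (fdr2 < alpha)


def run_de(
    cm: CountMatrix,
    comparison: tuple[str, str],
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> DEResult:
    """Run both callers on one comparison and combine them by consensus.

    log2FC is computed from group-mean FPM with the given pseudocount,
    oriented b relative to a (positive = up in group b).
    """
    ia, ib = _split(cm, comparison)
    p1, flag1 = nb_wald_test(cm, comparison)
    p2, flag2 = logcpm_moderated_t(cm, comparison)
    fdr1 = bh_fdr(p1)
    fdr2 = bh_fdr(p2)
    am = normalize_fpm(cm)
    lfc = log2_fold_change(
        am.fpm[:, ia].mean(axis=1), am.fpm[:, ib].mean(axis=1), pseudocount
    )
    table = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "log2fc": lfc,
            "p_nb_wald": p1,
            "p_mod_t": p2,
            "fdr_nb_wald": fdr1,
            "fdr_mod_t": fdr2,
            "consensus_deg": consensus_deg(fdr1, fdr2, alpha),
            "degenerate": flag1 | flag2,
        }
    )
    return DEResult(
        comparison=f"{comparison[0]}_vs_{comparison[1]}",
        group_a=comparison[0],
        group_b=comparison[1],
        alpha=alpha,
        table=table,
    )
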