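import numpy as np
import pytest

from txrescue.counts import CountMatrix


@pytest.fixture
def toy_counts() -> CountMatrix:
    """2 genes x 3 samples, one sample per group plus design."""
    return CountMatrix(
        gene_ids=["g1", "g2"],
        sample_ids=["c1", "c2", "d1"],
        counts=np.array([[10, 12, 40], [5, 6, 7]]),
        design={"c1": "control", "c2": "control", "d1": "disease"},
    )


@pytest.fixture
def three_group_counts() -> CountMatrix:
    """Small 4/5/5 study with NB noise and one strongly rescued gene."""
    rng = np.random.default_rng(5)
    n_genes = 60
    sizes = {"control": 4, "disease": 5, "disease_drug": 5}
    sample_ids, groups = [], []
    for g, k in sizes.items():
        for i in range(k):
            sample_ids.append(f"{g}_{i+1}")
            groups.append(g)
    base = rng.lognormal(np.log(200), 1.0, size=n_genes)
    mult = {"control": np.ones(n_genes), "disease": np.ones(n_genes),
            "disease_drug": np.ones(n_genes)}
    mult["disease"][0] = 8.0  # rescued gene: strong disease shift, drug restored
    r = 1 / 0.05
    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    for j, grp in enumerate(groups):
        mu = base * mult[grp] * 50
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=sample_ids,
        counts=counts,
        design=dict(zip(sample_ids, groups)),
    )


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Independent Benjamini–Hochberg step-up: textbook formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
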