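"""Count-matrix I/O, FPM normalization, biotype filtering and PCA sample QC.

The central container is :class:`CountMatrix`: integer fragment counts over
genes x samples, with a design mapping each sample to one of the three study
groups (``control``, ``disease``, ``disease_drug``).  Abundances are expressed
as FPM — fragments per million counted fragments — i.e. per-sample
counts-per-million with no gene-length correction; the per-sample library size
is the column sum of the matrix at the point of normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

GROUPS = ("control", "disease", "disease_drug")

MissingPolicy = Literal["drop", "keep", "error"]


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) with a group design."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    design: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts are not allowed")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        missing = [s for s in self.sample_ids if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene id: {g!r}")
            seen.add(g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def group_indices(self, group: str) -> np.ndarray:
        """Column indices of the samples assigned to *group*."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.design[s] == group],
            dtype=int,
        )

    def groups(self) -> list[str]:
        """Group labels present in the design, in first-appearance order."""
        out: list[str] = []
        for s in self.sample_ids:
            g = self.design[s]
            if g not in out:
                out.append(g)
        return out

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            counts=self.counts[:, idx].copy(),
            design={s: self.design[s] for s in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class AbundanceMatrix:
    """FPM abundances (genes x samples); columns sum to 1e6."""

    gene_ids: list[str]
    sample_ids: list[str]
    fpm: np.ndarray
    design: dict[str, str]

    def group_indices(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.design[s] == group],
            dtype=int,
        )

    def group_values(self, gene_index: int, group: str) -> np.ndarray:
        """FPM vector of one gene within one group."""
        return self.fpm[gene_index, self.group_indices(group)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fpm, index=self.gene_ids, columns=self.sample_ids)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class SampleQCReport:
    """Per-sample PCA coordinates and centroid-distance outlier flags."""

    sample_ids: list[str]
    groups: list[str]
    pc1: np.ndarray
    pc2: np.ndarray
    centroid_distance: np.ndarray
    flagged: np.ndarray
    multiplier: float

    @property
    def flagged_samples(self) -> list[str]:
        return [s for s, f in zip(self.sample_ids, self.flagged) if f]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "multiplier": self.multiplier,
            "samples": [
                {
                    "sample_id": s,
                    "group": g,
                    "pc1": float(p1),
                    "pc2": float(p2),
                    "centroid_distance": float(d),
                    "flagged": bool(f),
                }
                for s, g, p1, p2, d, f in zip(
                    self.sample_ids,
                    self.groups,
                    self.pc1,
                    self.pc2,
                    self.centroid_distance,
                    self.flagged,
                )
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, group) into a design map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample in design: {dup!r}")
    return dict(zip(df["sample_id"], df["group"]))


def read_biotypes(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (gene_id, biotype) into an annotation map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "biotype"], dtype=str)
    return dict(zip(df["gene_id"], df["biotype"]))


def read_counts(path: str | Path, design: Mapping[str, str]) -> CountMatrix:
    """Read a featureCounts-style TSV: gene-id column then one integer column
    per sample (header row gives sample ids).

    Every sample column must be covered by *design*; negative, non-integer or
    duplicated-gene rows are rejected with an error naming the offender.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("counts file needs a gene-id column and >=1 sample column")
    gene_col = df.columns[0]
    sample_ids = [str(c) for c in df.columns[1:]]
    missing = [s for s in sample_ids if s not in design]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    gene_ids = df[gene_col].astype(str).tolist()
    dup = df[gene_col][df[gene_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id: {dup.iloc[0]!r}")
    values = df[df.columns[1:]]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"malformed count for gene {gene_ids[r]!r}, sample {sample_ids[c]!r}")
    arr = numeric.to_numpy()
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative count for gene {gene_ids[r]!r}, sample {sample_ids[c]!r}")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        r, c = np.argwhere(np.mod(arr, 1) != 0)[0]
        raise ValueError(f"non-integer count for gene {gene_ids[r]!r}, sample {sample_ids[c]!r}")
    return CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts=arr.astype(np.int64),
        design={s: design[s] for s in sample_ids},
    )


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix back to the TSV layout read_counts expects."""
    df = cm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def normalize_fpm(cm: CountMatrix) -> AbundanceMatrix:
    """Normalize counts to fragments per million counted fragments.

    fpm[g, s] = counts[g, s] / sum_g counts[g, s] * 1e6, so every sample
    column sums to exactly one million.  A sample with zero total counts has
    no defined abundance and is rejected.
    """
    totals = cm.counts.sum(axis=0).astype(float)
    zero = np.where(totals == 0)[0]
    if len(zero):
        raise ValueError(f"sample {cm.sample_ids[zero[0]]!r} has all-zero counts")
    fpm = cm.counts / totals[None, :] * 1e6
    return AbundanceMatrix(
        gene_ids=list(cm.gene_ids),
        sample_ids=list(cm.sample_ids),
        fpm=fpm,
        design=dict(cm.design),
    )


def filter_protein_coding(
    cm: CountMatrix,
    annotation: Mapping[str, str],
    missing_policy: MissingPolicy = "drop",
) -> CountMatrix:
    """Restrict the matrix to protein-coding genes.

    Genes absent from *annotation* are handled by *missing_policy*:
    ``drop`` (default) removes them, ``keep`` retains them, ``error`` raises.
    Idempotent; sample set unchanged.
    """
    keep: list[int] = []
    for i, g in enumerate(cm.gene_ids):
        biotype = annotation.get(g)
        if biotype is None:
            if missing_policy == "error":
                raise ValueError(f"gene {g!r} has no biotype annotation")
            if missing_policy == "keep":
                keep.append(i)
            continue
        if biotype == "protein_coding":
            keep.append(i)
    return CountMatrix(
        gene_ids=[cm.gene_ids[i] for i in keep],
        sample_ids=list(cm.sample_ids),
        counts=cm.counts[keep, :].copy(),
        design=dict(cm.design),
    )


def pca_sample_qc(am: AbundanceMatrix, multiplier: float = 3.0) -> SampleQCReport:
    """Flag samples far from their group centroid in PC1/PC2 space.

    Works on log2(FPM + 1).  A sample is flagged when its Euclidean distance
    to its own group centroid (first two principal components) exceeds
    ``multiplier`` times the median within-group centroid distance over all
    samples.  Groups with fewer than three members are never flagged: with
    n = 2 both samples sit symmetrically around the centroid and the rule
    would be meaningless.
    """
    n_genes, n_samples = am.fpm.shape
    if n_genes < 2:
        raise ValueError("PCA sample QC needs at least 2 genes")
    if n_samples < 3:
        raise ValueError("PCA sample QC needs at least 3 samples")
    x = np.log2(am.fpm + 1.0).T  # samples x genes
    n_comp = min(2, n_samples - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    if n_comp == 1:
        coords = np.column_stack([coords[:, 0], np.zeros(n_samples)])

    groups = [am.design[s] for s in am.sample_ids]
    dist = np.zeros(n_samples)
    for g in set(groups):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        centroid = coords[idx].mean(axis=0)
        dist[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    med = float(np.median(dist))
    # absolute floor so numerically-identical samples are never flagged
    tol = 1e-9 * (1.0 + float(np.abs(coords).max()))
    sizes = {g: groups.count(g) for g in set(groups)}
    flagged = np.array(
        [d > multiplier * med + tol and sizes[g] >= 3 for d, g in zip(dist, groups)],
        dtype=bool,
    )
    return SampleQCReport(
        sample_ids=list(am.sample_ids),
        groups=groups,
        pc1=coords[:, 0],
        pc2=coords[:, 1],
        centroid_distance=dist,
        flagged=flagged,
        multiplier=multiplier,
    )
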