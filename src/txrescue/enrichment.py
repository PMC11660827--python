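"""GO over-representation analysis and common-child-term identification.

The ontology is held as a DAG with child -> parent ``is_a`` edges
(``part_of`` opt-in).  Annotations follow the true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor, so direct
annotations are propagated up the graph before testing.

Enrichment of a query set against a background uses the one-sided
hypergeometric tail P(X >= k); multiple-testing adjustment defaults to
Bonferroni (closer in stringency to g:SCS-style corrections than BH), with
BH selectable.  The enrichment score is fold enrichment (k/n)/(K/N).

"Common child terms" name the shared biological theme of a significant term
set: significant terms that are proper descendants of at least ``k_min``
other significant terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy import stats

from txrescue.de import bh_fdr


@dataclass
class GODag:
    """Ontology DAG; ``graph`` edges point child -> parent."""

    graph: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology graph is cyclic: {cycle}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from *term* (excluding itself)."""
        if term not in self.graph:
            raise KeyError(f"unknown term: {term!r}")
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """All terms below *term* (excluding itself)."""
        if term not in self.graph:
            raise KeyError(f"unknown term: {term!r}")
        return nx.ancestors(self.graph, term)


@dataclass
class CommonChildReport:
    """Significant descendants of multiple significant ancestors."""

    k_min: int
    common_children: dict[str, list[str]]  # term -> sorted significant ancestors
    leaves: list[str]  # significant terms with no significant descendant

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "k_min": self.k_min,
                "common_children": self.common_children,
                "leaves": self.leaves,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def parse_obo(path: str | Path, include_part_of: bool = False) -> GODag:
    """Parse an OBO 1.2/1.4 file into a :class:`GODag`.

    Keeps ``is_a`` edges (and ``part_of`` when requested); obsolete terms are
    dropped; a cyclic graph is rejected.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=True)
    keep_keys = {"is_a"} | ({"part_of"} if include_part_of else set())
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes)
    for child, parent, key in multi.edges(keys=True):
        if key in keep_keys:
            g.add_edge(child, parent)
    names = {n: d.get("name", "") for n, d in multi.nodes(data=True)}
    namespaces = {n: d.get("namespace", "") for n, d in multi.nodes(data=True)}
    return GODag(graph=g, names=names, namespaces=namespaces)


def write_obo(dag: GODag, path: str | Path) -> None:
    """Serialize a :class:`GODag` back to minimal OBO stanzas (is_a only)."""
    lines = ["format-version: 1.2", "ontology: txrescue-dag", ""]
    for term in sorted(dag.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.names.get(term, term)}")
        ns = dag.namespaces.get(term)
        if ns:
            lines.append(f"namespace: {ns}")
        for parent in sorted(dag.graph.successors(term)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (term_id, gene_id) into term -> gene-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"], dtype=str)
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term_id"], df["gene_id"]):
        out.setdefault(term, set()).add(gene)
    return out


def annotate_with_ancestors(
    dag: GODag, direct: Mapping[str, Iterable[str]]
) -> dict[str, set[str]]:
    """Propagate direct annotations up the DAG (true-path rule).

    Each term's gene set becomes the union of its own direct annotations and
    those of all its descendants.
    """
    unknown = [t for t in direct if t not in dag.graph]
    if unknown:
        raise KeyError(f"unknown term id: {unknown[0]!r}")
    out: dict[str, set[str]] = {t: set(genes) for t, genes in direct.items()}
    # child -> parent edges: topological order visits children before parents
    for term in nx.topological_sort(dag.graph):
        genes = out.get(term)
        if not genes:
            continue
        for parent in dag.graph.successors(term):
            out.setdefault(parent, set()).update(genes)
    return out


def hypergeom_enrich(
    query: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term.

    For each term with K annotated background genes, k of which are in the
    query of size n drawn from a background of size N, p = P(X >= k) for
    X ~ Hypergeometric(N, K, n).  Terms with K = 0 are skipped.  The
    enrichment score is (k/n)/(K/N).
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("empty query gene set")
    stray = query - background
    if stray:
        raise ValueError(f"query gene outside background: {sorted(stray)[0]!r}")
    n, N = len(query), len(background)
    rows = []
    for term, genes in annotations.items():
        term_genes = set(genes) & background
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": min(p, 1.0),
                "enrichment_score": (k / n) / (K / N),
            }
        )
    return pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p", "enrichment_score"])


def adjust_pvalues(results: pd.DataFrame, method: str = "bonferroni") -> pd.DataFrame:
    """Add a ``p_adj`` column (``bonferroni`` default, ``bh`` selectable)."""
    out = results.copy()
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        return out
    p = out["p"].to_numpy()
    if method == "bonferroni":
        out["p_adj"] = (p * len(p)).clip(max=1.0)
    elif method == "bh":
        out["p_adj"] = bh_fdr(p)
    else:
        raise ValueError(f"unknown adjustment method: {method!r}")
    return out


def significant_terms(results: pd.DataFrame, alpha: float = 1e-6) -> set[str]:
    """Terms with adjusted p <= alpha (inclusive boundary)."""
    if "p_adj" not in results.columns:
        raise ValueError("run adjust_pvalues first (no p_adj column)")
    return set(results.loc[results["p_adj"] <= alpha, "term_id"])


def common_child_terms(
    dag: GODag, significant: Iterable[str], k_min: int = 2
) -> CommonChildReport:
    """Identify significant terms descending from >= k_min significant terms.

    Also flags the leaves of the significant subgraph (significant terms with
    no significant proper descendant) — the most specific shared themes.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    significant = set(significant)
    unknown = significant - dag.terms
    if unknown:
        raise KeyError(f"unknown term: {sorted(unknown)[0]!r}")
    common: dict[str, list[str]] = {}
    leaves: list[str] = []
    for term in sorted(significant):
        sig_ancestors = dag.ancestors(term) & significant
        if len(sig_ancestors) >= k_min:
            common[term] = sorted(sig_ancestors)
        if not (dag.descendants(term) & significant):
            leaves.append(term)
    return CommonChildReport(k_min=k_min, common_children=common, leaves=leaves)
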