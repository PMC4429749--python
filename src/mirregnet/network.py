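"""miRNA-centric regulatory network assembly.

Layers:

* TF -> miRNA edges from coTFBS over-representation,
* miRNA -> target edges from miRNA-target interactions (MTIs), with the
  expression correlation between the miRNA and the target attached,
* gene -> gene edges expanded by depth-first search from each direct
  target, yielding the indirect targets (the downstream gene circuit),
* GO-term enrichment of the miRNA-mediated gene set.

The assembled network is a typed ``networkx.DiGraph`` exportable to
SIF, GraphML and Cytoscape JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import pcc
from .tfbs import CoTFBSStat, hypergeom_pvalue

__all__ = [
    "MTI",
    "GeneGraph",
    "SpanningForest",
    "GoEnrichmentRow",
    "RegulatoryNetwork",
    "read_mti_tsv",
    "read_edge_tsv",
    "read_go_tsv",
    "mti_correlation",
    "dedupe_mtis",
    "expand_indirect_targets",
    "go_enrichment",
    "build_network",
    "export_network",
    "import_graphml",
]

EVIDENCE_LEVELS = ("verified", "putative")


@dataclass(frozen=True)
class MTI:
    """A miRNA-target interaction, experimentally verified or predicted."""

    mirna: str
    target: str
    evidence: str = "putative"
    source: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(
                f"evidence must be one of {EVIDENCE_LEVELS}, "
                f"got {self.evidence!r}")


class GeneGraph:
    """Directed gene-gene interaction graph (regulator -> regulatee).

    Duplicate edges collapse; self-edges are allowed (self-regulation
    occurs in real circuits and must not break traversal). Undirected
    input can be expanded to both directions.
    """

    def __init__(self, edges: Iterable[tuple[str, str]],
                 nodes: Iterable[str] = (), undirected: bool = False):
        self.adj: dict[str, list[str]] = {}
        seen: set[tuple[str, str]] = set()
        for u, v in edges:
            pairs = [(u, v), (v, u)] if undirected and u != v else [(u, v)]
            for a, b in pairs:
                if (a, b) not in seen:
                    seen.add((a, b))
                    self.adj.setdefault(a, []).append(b)
                    self.adj.setdefault(b, [])
        for n in nodes:
            self.adj.setdefault(n, [])
        for children in self.adj.values():
            children.sort()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.adj)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u in sorted(self.adj) for v in self.adj[u]]

    def adjacency_matrix(self) -> tuple[np.ndarray, list[str]]:
        """0/1 matrix with entry (i, j) = 1 iff edge node_i -> node_j."""
        nodes = self.nodes
        index = {n: i for i, n in enumerate(nodes)}
        mat = np.zeros((len(nodes), len(nodes)), dtype=int)
        for u, v in self.edges:
            mat[index[u], index[v]] = 1
        return mat, nodes

    def __contains__(self, node: str) -> bool:
        return node in self.adj


@dataclass
class SpanningForest:
    """DFS spanning forest rooted at the direct targets.

    ``depth`` maps every reached node to its depth (0 for roots);
    ``tree_edges`` are the DFS tree edges; ``indirect`` is the reachable
    set minus the direct targets.
    """

    roots: list[str]
    depth: dict[str, int]
    tree_edges: list[tuple[str, str]]

    @property
    def nodes(self) -> set[str]:
        return set(self.depth)

    @property
    def indirect(self) -> set[str]:
        return set(self.depth) - set(self.roots)


def expand_indirect_targets(direct_targets: Iterable[str],
                            graph: GeneGraph) -> SpanningForest:
    """Depth-first expansion from each direct target until no child is new.

    Every reachable gene is visited exactly once, so feedback loops and
    self-edges terminate. Traversal is deterministic: roots and children
    in lexicographic order. Direct targets missing from the graph are
    skipped with a warning.
    """
    roots = sorted(set(direct_targets))
    known = [r for r in roots if r in graph]
    missing = set(roots) - set(known)
    if missing:
        warnings.warn(
            f"direct targets absent from the gene graph, skipped: "
            f"{sorted(missing)}")
    depth: dict[str, int] = {}
    tree_edges: list[tuple[str, str]] = []
    for root in known:
        if root in depth:
            continue
        depth[root] = 0
        stack = [(root, iter(graph.adj[root]))]
        while stack:
            node, children = stack[-1]
            for child in children:
                if child not in depth:
                    depth[child] = depth[node] + 1
                    tree_edges.append((node, child))
                    stack.append((child, iter(graph.adj[child])))
                    break
            else:
                stack.pop()
    return SpanningForest(known, depth, tree_edges)


@dataclass(frozen=True)
class GoEnrichmentRow:
    """One GO term's hypergeometric enrichment in a query gene set."""

    term: str
    name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    adjusted_p: float | None = None


def go_enrichment(query_genes: Iterable[str],
                  annotations: Mapping[str, set[str]] | pd.DataFrame,
                  background: Iterable[str] | None = None,
                  min_term_size: int = 2,
                  adjust: str = "none",
                  term_names: Mapping[str, str] | None = None,
                  namespaces: Mapping[str, str] | None = None
                  ) -> list[GoEnrichmentRow]:
    """Upper-tail hypergeometric GO-term enrichment of a gene set.

    ``annotations`` maps gene -> set of term ids (a 2-column DataFrame
    of gene, term also works); ancestor propagation is the caller's
    responsibility. The background defaults to all annotated genes.
    Rows are sorted by p ascending; ``adjust='BH'`` adds
    Benjamini-Hochberg adjusted p-values.
    """
    if isinstance(annotations, pd.DataFrame):
        ann: dict[str, set[str]] = {}
        for gene, term in annotations.iloc[:, :2].itertuples(index=False):
            ann.setdefault(str(gene), set()).add(str(term))
        annotations = ann
    bg = set(background) if background is not None else set(annotations)
    query = set(query_genes) & bg
    if not query:
        raise ValueError("query is empty after intersecting the background")

    term_genes: dict[str, set[str]] = {}
    for gene in bg:
        for term in annotations.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    N, n = len(bg), len(query)
    rows = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(genes & query)
        p = hypergeom_pvalue(N, K, n, k)
        rows.append(GoEnrichmentRow(
            term, (term_names or {}).get(term, term),
            (namespaces or {}).get(term, ""), k, n, K, N, p))
    rows.sort(key=lambda r: (r.p_value, r.term))
    if adjust == "BH" and rows:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        rows = [GoEnrichmentRow(r.term, r.name, r.namespace, r.k, r.n,
                                r.K, r.N, r.p_value, float(a))
                for r, a in zip(rows, adj)]
    elif adjust != "none":
        raise ValueError("adjust must be 'none' or 'BH'")
    return rows


def mti_correlation(mti: MTI, mirna_expr: pd.DataFrame,
                    gene_expr: pd.DataFrame) -> float | None:
    """Pearson correlation of a miRNA's and its target's expression.

    Missing expression for either side is a value (None), not an error:
    the MTI edge is kept and flagged as lacking expression support.
    """
    if mti.mirna not in mirna_expr.index or mti.target not in gene_expr.index:
        return None
    return pcc(mirna_expr.loc[mti.mirna].to_numpy(dtype=float),
               gene_expr.loc[mti.target].to_numpy(dtype=float))


def dedupe_mtis(mtis: Iterable[MTI]) -> list[MTI]:
    """Merge duplicate (miRNA, target) pairs; 'verified' dominates."""
    best: dict[tuple[str, str], MTI] = {}
    for m in mtis:
        key = (m.mirna, m.target)
        prev = best.get(key)
        if prev is None:
            best[key] = m
        else:
            evidence = "verified" if "verified" in (m.evidence, prev.evidence) \
                else "putative"
            sources = ";".join(sorted({s for s in (prev.source, m.source) if s}))
            score = prev.score if prev.score is not None else m.score
            best[key] = MTI(m.mirna, m.target, evidence, sources, score)
    return [best[k] for k in sorted(best)]


NODE_TYPES = ("TF", "miRNA", "direct_target", "indirect_target")


@dataclass
class RegulatoryNetwork:
    """Typed regulatory graph around one or more miRNAs."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(tf_mirna: Sequence[tuple[str, str, CoTFBSStat | None]],
                  mtis: Sequence[MTI],
                  forest: SpanningForest | None = None,
                  correlations: Mapping[tuple[str, str], float | None]
                  | None = None) -> RegulatoryNetwork:
    """Assemble the typed network from its three relation layers.

    Duplicate MTIs are merged first ('verified' dominates). Gene-gene
    edges come from the DFS forest's tree edges; genes reached there but
    never named as direct targets become ``indirect_target`` nodes.
    Nodes are added in sorted order so serialisation is deterministic.
    """
    g = nx.DiGraph()
    mtis = dedupe_mtis(mtis)
    correlations = correlations or {}

    direct = {m.target for m in mtis}
    indirect = (forest.indirect - direct) if forest is not None else set()

    for tf, _, _ in sorted(tf_mirna, key=lambda t: t[0]):
        if tf:
            g.add_node(tf, type="TF")
    for m in sorted({m.mirna for m in mtis}
                    | {mi for _, mi, _ in tf_mirna if mi}):
        g.add_node(m, type="miRNA")
    for t in sorted(direct):
        g.add_node(t, type="direct_target")
    for t in sorted(indirect):
        g.add_node(t, type="indirect_target")

    for tf, mirna, stat in tf_mirna:
        if tf not in g or mirna not in g:
            raise ValueError(f"dangling TF->miRNA edge endpoint: "
                             f"{tf!r} -> {mirna!r}")
        attrs = {"interaction": "regulates"}
        if stat is not None:
            attrs.update(frequency=stat.frequency, p_value=stat.p_value,
                         N=stat.N, K=stat.K, n=stat.n, k=stat.k)
        g.add_edge(tf, mirna, **attrs)
    for m in mtis:
        corr = correlations.get((m.mirna, m.target))
        g.add_edge(m.mirna, m.target, interaction="targets",
                   evidence=m.evidence, source=m.source,
                   **({"correlation": float(corr)} if corr is not None
                      else {}))
    if forest is not None:
        for u, v in forest.tree_edges:
            if u not in g:
                g.add_node(u, type="indirect_target")
            if v not in g:
                g.add_node(v, type="indirect_target")
            g.add_edge(u, v, interaction="interacts",
                       depth=forest.depth[v])
    return RegulatoryNetwork(g)


_SIF_TYPES = {"regulates", "targets", "interacts"}


def export_network(network: RegulatoryNetwork, path, fmt: str = "SIF") -> None:
    """Write a network as SIF, GraphML or Cytoscape JSON.

    GraphML carries all node/edge attributes and round-trips exactly
    through :func:`import_graphml`.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        warnings.warn("exporting an empty network")
    if fmt == "SIF":
        with open(path, "wt") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                kind = data.get("interaction", "interacts")
                if kind not in _SIF_TYPES:
                    kind = "interacts"
                fh.write(f"{u}\t{kind}\t{v}\n")
            for node in sorted(n for n in g.nodes if g.degree(n) == 0):
                fh.write(f"{node}\n")
    elif fmt == "GraphML":
        nx.write_graphml(g, path)
    elif fmt == "CytoscapeJSON":
        with open(path, "wt") as fh:
            json.dump(nx.cytoscape_data(g), fh, indent=1, sort_keys=True)
    else:
        raise ValueError(
            f"unknown format {fmt!r}; supported: SIF, GraphML, CytoscapeJSON")


def import_graphml(path) -> RegulatoryNetwork:
    g = nx.read_graphml(path)
    # reader bookkeeping attrs, not part of the network
    g.graph.pop("node_default", None)
    g.graph.pop("edge_default", None)
    return RegulatoryNetwork(g)


# ---------------------------------------------------------------------------
# Readers for the tabular relation formats

def read_mti_tsv(path) -> list[MTI]:
    """Read MTIs from TSV with columns mirna, target, evidence, source[, score]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        if score is not None and pd.isna(score):
            score = None
        out.append(MTI(str(row.mirna), str(row.target),
                       str(row.evidence), str(getattr(row, "source", "")),
                       float(score) if score is not None else None))
    return out


def read_edge_tsv(path, undirected: bool = False) -> GeneGraph:
    """Read gene-gene edges from 2-column TSV or 3-column SIF."""
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if not parts or parts == [""] or parts[0].startswith("#"):
                continue
            if len(parts) >= 3 and parts[1] in _SIF_TYPES:
                edges.append((parts[0], parts[2]))
            else:
                edges.append((parts[0], parts[1]))
    return GeneGraph(edges, undirected=undirected)


def read_go_tsv(path) -> dict[str, set[str]]:
    """Read 2-column (gene, term) annotations into gene -> terms."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "term"])
    ann: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False):
        ann.setdefault(str(gene), set()).add(str(term))
    return ann
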