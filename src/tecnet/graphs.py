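"""Gene-graph construction: threshold sweep, selection, and summaries.

A covariation matrix becomes an undirected gene graph by keeping every
pair with |score| >= threshold as an edge (optionally weighted by
|score|) and, usually, discarding isolated nodes.  The working threshold
is chosen by sweeping a grid and maximizing the number of multi-node
connected components — the point where the graph balances sparsity
against modular structure, before components start merging into one
giant component.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components as _sp_components

from .matrices import CovariationMatrix

__all__ = [
    "build_network",
    "sweep_thresholds",
    "select_threshold",
    "graph_summary",
    "largest_component",
    "ThresholdSweepResult",
    "GraphSummary",
    "write_edgelist",
    "read_edgelist",
]


def build_network(
    cov: CovariationMatrix,
    threshold: float,
    mode: str = "weighted",
    drop_isolated: bool = True,
    strict: bool = False,
) -> nx.Graph:
    """Threshold a covariation matrix into a gene graph.

    An edge (i, j), i != j, is present iff |score_ij| >= threshold
    (or > threshold with ``strict=True``).  In ``weighted`` mode the edge
    carries ``weight=|score_ij|``; ``binary`` mode stores no weights.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    if mode not in ("weighted", "binary"):
        raise ValueError("mode must be 'weighted' or 'binary'")

    a = np.abs(cov.scores)
    mask = (a > threshold) if strict else (a >= threshold)
    np.fill_diagonal(mask, False)
    mask &= np.isfinite(cov.scores)
    ii, jj = np.nonzero(np.triu(mask, k=1))

    g = nx.Graph(mode=mode, threshold=float(threshold))
    g.add_nodes_from(cov.gene_ids)
    genes = np.asarray(cov.gene_ids)
    if mode == "weighted":
        g.add_weighted_edges_from(zip(genes[ii], genes[jj], a[ii, jj]))
    else:
        g.add_edges_from(zip(genes[ii], genes[jj]))
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


@dataclass
class ThresholdSweepResult:
    """Per-threshold component/node/edge counts over a sweep grid."""

    grid: list[float]
    multi_node_components: list[int]
    connected_nodes: list[int]
    edges: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.grid,
                "multi_node_components": self.multi_node_components,
                "connected_nodes": self.connected_nodes,
                "edges": self.edges,
            }
        )


DEFAULT_GRID = [round(t, 2) for t in np.arange(0.50, 0.951, 0.01)]


def sweep_thresholds(
    cov: CovariationMatrix, grid: list[float] | None = None, strict: bool = False
) -> ThresholdSweepResult:
    """Count multi-node components, connected nodes, and edges per threshold.

    A multi-node component is a connected component with >= 2 nodes, i.e.
    total components minus isolated nodes.
    """
    if grid is None:
        grid = DEFAULT_GRID
    if len(grid) == 0:
        raise ValueError("empty threshold grid")
    if any(not 0.0 < t < 1.0 for t in grid):
        raise ValueError("grid values must lie strictly between 0 and 1")
    if list(grid) != sorted(grid):
        raise ValueError("grid must be sorted ascending")

    a = np.abs(cov.scores).copy()
    np.fill_diagonal(a, 0.0)
    multi, nodes, edges = [], [], []
    for t in grid:
        mask = (a > t) if strict else (a >= t)
        deg = mask.sum(axis=1)
        n_comp, labels = _sp_components(csr_array(mask), directed=False)
        sizes = np.bincount(labels)
        multi.append(int((sizes >= 2).sum()))
        nodes.append(int((deg > 0).sum()))
        edges.append(int(mask.sum()) // 2)
    return ThresholdSweepResult([float(t) for t in grid], multi, nodes, edges)


def select_threshold(sweep: ThresholdSweepResult) -> float:
    """Grid threshold maximizing multi-node components; ties -> largest t."""
    if not sweep.grid:
        raise ValueError("empty sweep")
    best_t, best_c = sweep.grid[0], sweep.multi_node_components[0]
    for t, c in zip(sweep.grid, sweep.multi_node_components):
        if c >= best_c:  # later (larger) threshold wins ties
            best_t, best_c = t, c
    return best_t


@dataclass
class GraphSummary:
    n: int
    m: int
    density: float


def graph_summary(g: nx.Graph) -> GraphSummary:
    """Node count, edge count, and density d = 2m / (n(n-1))."""
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValueError("graph summary requires at least 2 nodes")
    return GraphSummary(n, m, 2.0 * m / (n * (n - 1)))


def largest_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken toward the component containing the
    lexicographically smallest gene id.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(g))
    best_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == best_size]
    best = min(tied, key=lambda c: min(map(str, c)))
    return g.subgraph(best).copy()


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    rows = []
    for u, v, data in g.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rows.append((a, b, data.get("weight", 1.0)))
    rows.sort()
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edgelist(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for a, b, w in df.itertuples(index=False):
        g.add_edge(str(a), str(b), weight=float(w))
    return g
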