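"""Community structure: Louvain partitions, maximal cliques, subgraph overlap.

Louvain modularity optimization runs on the weighted graph (edge weights
as modularity weights), conventionally on the largest connected
component; the resulting cluster count is seed-sensitive.  Maximal
cliques — the most cohesive units of a covariation network — are
enumerated by the pivoting Bron-Kerbosch algorithm on the binarized
graph, since clique membership is weight-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "louvain_clusters",
    "maximal_cliques",
    "induced_subgraph_compare",
    "CommunityPartition",
    "CliqueSet",
    "SubgraphComparison",
]


@dataclass
class CommunityPartition:
    """Gene -> cluster assignment with sizes and modularity."""

    labels: dict[str, int]
    sizes: list[int]
    modularity: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["gene", "cluster"]
        )


def louvain_clusters(
    g: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Louvain modularity clustering on edge weights.

    Cluster ids are assigned in decreasing order of cluster size (ties by
    smallest member gene id) so the labeling is stable for a fixed seed.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=int(seed)
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(map(str, c))))
    labels = {str(u): i for i, c in enumerate(comms) for u in c}
    mod = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
    return CommunityPartition(labels, [len(c) for c in comms], float(mod))


@dataclass
class CliqueSet:
    """All maximal cliques, largest first."""

    cliques: list[list[str]] = field(repr=False)

    @property
    def largest(self) -> list[str]:
        return self.cliques[0] if self.cliques else []

    def __len__(self) -> int:
        return len(self.cliques)


def maximal_cliques(g: nx.Graph) -> CliqueSet:
    """Enumerate all maximal cliques (pivoting Bron-Kerbosch).

    Cliques are returned sorted by size descending, then lexicographically
    by their sorted member lists.
    """
    cliques = [sorted(map(str, c)) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-len(c), c))
    return CliqueSet(cliques)


@dataclass
class SubgraphComparison:
    """Edge sets of two induced subgraphs split into shared/A-only/B-only."""

    genes: list[str]
    shared_edges: set[tuple[str, str]]
    edges_only_a: set[tuple[str, str]]
    edges_only_b: set[tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(a, b, "shared") for a, b in sorted(self.shared_edges)]
            + [(a, b, "A_only") for a, b in sorted(self.edges_only_a)]
            + [(a, b, "B_only") for a, b in sorted(self.edges_only_b)]
        )
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "origin"])


def _induced_edges(g: nx.Graph, genes: set[str]) -> set[tuple[str, str]]:
    out = set()
    for u, v in g.subgraph(n for n in g if str(n) in genes).edges():
        a, b = sorted((str(u), str(v)))
        out.add((a, b))
    return out


def induced_subgraph_compare(
    ga: nx.Graph, gb: nx.Graph, genes: Sequence[str]
) -> SubgraphComparison:
    """Partition the induced edges over a gene set into shared / A / B only."""
    if len(genes) == 0:
        raise ValueError("empty gene list")
    gset = set(map(str, genes))
    ea, eb = _induced_edges(ga, gset), _induced_edges(gb, gset)
    return SubgraphComparison(sorted(gset), ea & eb, ea - eb, eb - ea)
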