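"""Node- and graph-level topology: clustering, rich club, paths, centralities.

Definitions used throughout (u a node, deg its degree, w edge weights):

- unweighted clustering(u) = 2 Tr(u) / (deg(u) (deg(u) - 1)) with Tr(u)
  the number of triangles through u;
- weighted clustering replaces each triangle by the geometric mean of
  its three weights after normalizing by the maximum weight in the
  graph, so it reduces to the unweighted value when weights are equal;
- rich-club coefficient phi(k) = 2 E_>k / (N_>k (N_>k - 1)): the density
  of the subgraph induced by nodes of degree > k, optionally normalized
  by its mean over expected-degree null replicates;
- node strength = sum of incident weights; closeness and betweenness use
  shortest paths, with similarity weights turned into distances by a
  configurable transform (reciprocal by default).

Nodes of degree < 2 get clustering 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import stream
from .nullmodels import expected_degree_graph

__all__ = [
    "clustering_coefficients",
    "rich_club_curve",
    "path_length_distribution",
    "centralities",
    "RichClubCurve",
    "PathLengthDistribution",
]


def _is_weighted(g: nx.Graph) -> bool:
    return all("weight" in d for _, _, d in g.edges(data=True)) and g.number_of_edges() > 0


def clustering_coefficients(g: nx.Graph, weighted: bool = False) -> pd.DataFrame:
    """Per-node clustering table: gene, degree, triangles, coefficient."""
    if weighted and not _is_weighted(g):
        raise ValueError("weighted clustering requires edge weights")
    coeff = nx.clustering(g, weight="weight" if weighted else None)
    deg = dict(g.degree())
    if weighted:
        # triangle-intensity sum implied by the coefficient
        tri = {u: coeff[u] * deg[u] * (deg[u] - 1) / 2.0 for u in g}
    else:
        tri = nx.triangles(g)
    nodes = sorted(g.nodes(), key=str)
    return pd.DataFrame(
        {
            "gene": [str(u) for u in nodes],
            "degree": [deg[u] for u in nodes],
            "triangles": [tri[u] for u in nodes],
            "clustering": [coeff[u] for u in nodes],
        }
    )


@dataclass
class RichClubCurve:
    """phi(k) per degree cutoff, with optional null-mean normalization."""

    table: pd.DataFrame = field(repr=False)
    n_null: int = 0

    def phi(self, k: int) -> float:
        row = self.table.loc[self.table["k"] == k]
        return float(row["phi"].iloc[0]) if len(row) else float("nan")


def _phi_by_k(degrees: np.ndarray, edge_min_deg: np.ndarray, kmax: int):
    """phi(k) for k = 0..kmax-1 from degree and per-edge min-degree arrays."""
    n_gt = np.zeros(kmax, dtype=int)
    e_gt = np.zeros(kmax, dtype=int)
    deg_counts = np.bincount(degrees, minlength=kmax + 1)
    edge_counts = np.bincount(edge_min_deg, minlength=kmax + 1)
    # N_>k = #nodes with degree > k: suffix sums
    n_gt = deg_counts[::-1].cumsum()[::-1]
    e_gt_full = edge_counts[::-1].cumsum()[::-1]
    ks = np.arange(kmax)
    n = n_gt[ks + 1]  # nodes with degree >= k+1, i.e. > k
    e = e_gt_full[ks + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(n >= 2, 2.0 * e / (n * (n - 1.0)), np.nan)
    return ks, phi, e, n


def rich_club_curve(g: nx.Graph, n_null: int = 0, seed: int = 0) -> RichClubCurve:
    """Rich-club curve phi(k) for all k where at least 2 nodes exceed k.

    With ``n_null > 0`` the curve is normalized by the mean phi(k) over
    that many expected-degree (Chung-Lu) replicates generated from the
    observed degree sequence; elevated ratios at high k indicate a rich
    club beyond what the degree sequence alone implies.
    """
    deg = dict(g.degree())
    if not deg:
        raise ValueError("empty graph")
    degrees = np.array(list(deg.values()), dtype=int)
    kmax = int(degrees.max())
    if kmax == 0:
        raise ValueError("graph has no edges")
    edge_min = np.array([min(deg[u], deg[v]) for u, v in g.edges()], dtype=int)
    ks, phi, e_gt, n_gt = _phi_by_k(degrees, edge_min, kmax)

    table = pd.DataFrame({"k": ks, "N_gt_k": n_gt, "E_gt_k": e_gt, "phi": phi})
    if n_null > 0:
        rng = stream(seed, "rich_club_null")
        acc = np.zeros((n_null, kmax))
        for i in range(n_null):
            null = expected_degree_graph(degrees.tolist(),
                                         seed=int(rng.integers(2**31)))
            ndeg = np.array([d for _, d in null.degree()], dtype=int)
            nmax = int(ndeg.max()) if ndeg.size else 0
            row = np.full(kmax, np.nan)
            if nmax > 0:
                ndd = dict(null.degree())
                nedge = np.array(
                    [min(ndd[u], ndd[v]) for u, v in null.edges()], dtype=int
                )
                _, nphi, _, _ = _phi_by_k(ndeg, nedge, nmax)
                row[: min(kmax, nmax)] = nphi[: min(kmax, nmax)]
            acc[i] = row
        with np.errstate(invalid="ignore"):
            null_mean = np.nanmean(acc, axis=0)
        table["phi_null_mean"] = null_mean
        table["normalized_ratio"] = table["phi"] / null_mean
    return RichClubCurve(table, n_null)


@dataclass
class PathLengthDistribution:
    """Histogram of shortest-path hop counts within the largest component."""

    histogram: dict[int, int]
    mean: float
    n_component: int

    @property
    def n_pairs(self) -> int:
        return sum(self.histogram.values())


def path_length_distribution(g: nx.Graph) -> PathLengthDistribution:
    """Unweighted all-pairs shortest-path distribution, largest component."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    hist: dict[int, int] = {}
    total = 0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(sub):
        for d in dists.values():
            if d > 0:
                hist[d] = hist.get(d, 0) + 1
                total += d
                count += 1
    hist = {d: c // 2 for d, c in sorted(hist.items())}  # each pair seen twice
    count //= 2
    mean = (total / 2) / count if count else 0.0
    return PathLengthDistribution(hist, mean, len(comp))


_TRANSFORMS = {
    "reciprocal": lambda w: 1.0 / w,
    "one_minus": lambda w: 1.0 - w,
    "raw": lambda w: w,
}


def centralities(g: nx.Graph, distance_transform: str = "reciprocal") -> pd.DataFrame:
    """Strength, closeness, and betweenness per node.

    Strength is the sum of incident edge weights (the degree on a binary
    graph).  For the path-based centralities, similarity weights are
    converted to distances by ``distance_transform``: ``reciprocal``
    (1/w, the default — strong covariation means short distance),
    ``one_minus`` (1 - w), or ``raw`` (weights used as distances
    directly).  Closeness uses the component-size correction
    (n_c - 1)/(n - 1); betweenness is normalized by (n-1)(n-2)/2.
    """
    if distance_transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {distance_transform!r}")
    weighted = _is_weighted(g)
    nodes = sorted(g.nodes(), key=str)
    if weighted:
        h = g.copy()
        f = _TRANSFORMS[distance_transform]
        for u, v, d in h.edges(data=True):
            d["distance"] = f(d["weight"])
        strength = {u: s for u, s in h.degree(weight="weight")}
        closeness = nx.closeness_centrality(h, distance="distance")
        betweenness = nx.betweenness_centrality(h, weight="distance", normalized=True)
    else:
        strength = {u: float(d) for u, d in g.degree()}
        closeness = nx.closeness_centrality(g)
        betweenness = nx.betweenness_centrality(g, normalized=True)
    deg = dict(g.degree())
    return pd.DataFrame(
        {
            "gene": [str(u) for u in nodes],
            "degree": [deg[u] for u in nodes],
            "strength": [strength[u] for u in nodes],
            "closeness": [closeness[u] for u in nodes],
            "betweenness": [betweenness[u] for u in nodes],
        }
    )
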