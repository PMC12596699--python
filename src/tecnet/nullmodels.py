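"""Calibrated reference random graphs: BA, WS, and expected-degree models.

Three null models frame the topology of an observed gene graph:

- Barabasi-Albert preferential attachment (scale-free reference),
  initialized as an (m+1)-node star, each new node attaching m edges with
  probability proportional to current degree;
- Watts-Strogatz small-world (high clustering / short paths reference),
  a ring lattice with k nearest neighbors and low-probability rewiring;
- the expected-degree (Chung-Lu) model, with independent edges at
  probability d_u d_v / sum(d), matching a target degree sequence in
  expectation.

Calibration against an observed graph follows the conventions m ~
edge-to-vertex ratio (BA) and k ~ mean degree rounded to even (WS).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "barabasi_albert",
    "watts_strogatz",
    "expected_degree_graph",
    "ba_m_for",
    "ws_k_for",
]


def barabasi_albert(n: int, m: int, seed: int) -> nx.Graph:
    """BA graph on n nodes, m edges per new node, star initialization.

    The final edge count is exactly ``m + (n - m - 1) * m``: m edges from
    the initial star plus m for each of the n - m - 1 subsequent nodes.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n <= m + 1:
        raise ValueError("n must exceed m + 1")
    return nx.barabasi_albert_graph(n, m, seed=int(seed), initial_graph=nx.star_graph(m))


def watts_strogatz(n: int, k: int, p_rewire: float, seed: int) -> nx.Graph:
    """WS graph: ring lattice with k neighbors, each edge rewired w.p. p.

    Rewiring preserves the edge count, so m = n*k/2 for any p.
    """
    if k % 2 != 0:
        raise ValueError("k must be even")
    if not 2 <= k < n:
        raise ValueError("k must satisfy 2 <= k < n")
    if not 0.0 <= p_rewire <= 1.0:
        raise ValueError("p_rewire must lie in [0, 1]")
    return nx.watts_strogatz_graph(n, k, p_rewire, seed=int(seed))


def expected_degree_graph(degree_sequence: Sequence[int], seed: int) -> nx.Graph:
    """Chung-Lu graph: edge (u, v) with probability d_u d_v / sum(d)."""
    ds = list(int(d) for d in degree_sequence)
    if len(ds) == 0:
        raise ValueError("empty degree sequence")
    if any(d < 0 for d in ds):
        raise ValueError("degrees must be non-negative")
    total = sum(ds)
    if total > 0 and max(ds) ** 2 > total:
        warnings.warn(
            "max(d)^2 > sum(d): some edge probabilities clipped at 1; the "
            "realized degrees will undershoot the targets for the largest hubs",
            stacklevel=2,
        )
    return nx.expected_degree_graph(ds, seed=int(seed), selfloops=False)


def ba_m_for(g: nx.Graph) -> int:
    """BA m calibrated to a target graph: round(edge-to-vertex ratio)."""
    return max(1, round(g.number_of_edges() / g.number_of_nodes()))


def ws_k_for(g: nx.Graph) -> int:
    """WS k calibrated to a target graph: mean degree rounded to even."""
    mean_deg = 2.0 * g.number_of_edges() / g.number_of_nodes()
    k = 2 * round(mean_deg / 2.0)
    return max(2, k)


def degree_sequence_of(g: nx.Graph) -> list[int]:
    return [d for _, d in g.degree()]
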