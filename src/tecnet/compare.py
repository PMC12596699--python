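"""Cross-network comparison of two gene graphs built from covariation data.

The comparisons operate on the *overlapping* genes — those that survive
thresholding and isolated-node removal in both networks — and quantify
how differently each gene is embedded: neighborhood Jaccard similarity,
centrality imbalance, robustness of retained edges to the threshold, the
connectivity shift of a user-supplied gene list, and the relation between
connectivity and expression abundance/variability across tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import stream
from .matrices import CovariationMatrix
from .topology import centralities

__all__ = [
    "neighborhood_jaccard",
    "centrality_imbalance",
    "edge_retention_check",
    "connectivity_shift",
    "select_connectivity_extremes",
    "cv_by_abundance",
    "CVProfile",
]


def _overlap(ga: nx.Graph, gb: nx.Graph) -> list[str]:
    shared = set(map(str, ga.nodes())) & set(map(str, gb.nodes()))
    if not shared:
        raise ValueError("no overlapping genes between the two graphs")
    return sorted(shared)


def neighborhood_jaccard(ga: nx.Graph, gb: nx.Graph) -> pd.DataFrame:
    """Jaccard index of each overlapping gene's neighbor sets in A vs B.

    J(u) = |N_A(u) ∩ N_B(u)| / |N_A(u) ∪ N_B(u)|; a gene with the same
    single neighbor in both networks scores 1.
    """
    shared = _overlap(ga, gb)
    rows = []
    for u in shared:
        na = set(map(str, ga.neighbors(u)))
        nb = set(map(str, gb.neighbors(u)))
        union = na | nb
        j = len(na & nb) / len(union) if union else 0.0
        rows.append((u, len(na), len(nb), j))
    return pd.DataFrame(rows, columns=["gene", "degree_A", "degree_B", "jaccard"])


def centrality_imbalance(
    ga: nx.Graph, gb: nx.Graph, measure: str = "strength"
) -> pd.DataFrame:
    """Per-gene centrality in each network and their difference (A - B).

    Rows are the overlapping genes, ranked by |difference| descending.
    """
    if measure not in ("strength", "closeness", "betweenness"):
        raise ValueError(f"unknown measure {measure!r}")
    shared = _overlap(ga, gb)
    ca = centralities(ga).set_index("gene")[measure]
    cb = centralities(gb).set_index("gene")[measure]
    df = pd.DataFrame(
        {
            "gene": shared,
            f"{measure}_A": ca.reindex(shared).to_numpy(),
            f"{measure}_B": cb.reindex(shared).to_numpy(),
        }
    )
    df["difference"] = df[f"{measure}_A"] - df[f"{measure}_B"]
    return df.reindex(
        df["difference"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)


def edge_retention_check(
    ga: nx.Graph,
    cov_b: CovariationMatrix,
    gene: str,
    deltas: Sequence[float] = (0.1, 0.2),
) -> dict[float, float]:
    """Compare a gene's retained edge weights in A against its scores in B.

    For every edge (gene, v) retained in graph A, the gap
    |w_A - |score_B(gene, v)|| is computed, and the fraction of partners
    with gap > delta is reported per requested delta.  Partners missing
    from the B matrix are skipped with a warning.
    """
    if gene not in ga:
        raise ValueError(f"gene {gene!r} not present in graph A")
    pos = {g: i for i, g in enumerate(cov_b.gene_ids)}
    if gene not in pos:
        raise ValueError(f"gene {gene!r} not present in the B matrix")
    gi = pos[gene]
    gaps = []
    missing = 0
    for _, v, d in ga.edges(gene, data=True):
        if str(v) not in pos:
            missing += 1
            continue
        w_a = float(d.get("weight", 1.0))
        gaps.append(abs(w_a - abs(cov_b.scores[gi, pos[str(v)]])))
    if missing:
        warnings.warn(f"{missing} partner(s) of {gene} absent from the B matrix",
                      stacklevel=2)
    if not gaps:
        raise ValueError(f"gene {gene!r} has no comparable retained edges")
    arr = np.asarray(gaps)
    return {float(t): float(np.mean(arr > t)) for t in deltas}


def connectivity_shift(
    ga: nx.Graph, gb: nx.Graph, gene_list: Sequence[str]
) -> pd.DataFrame:
    """Degree of each listed gene in both networks (0 + flag when absent)."""
    if len(gene_list) == 0:
        raise ValueError("empty gene list")
    rows = []
    for g in map(str, gene_list):
        in_a, in_b = g in ga, g in gb
        rows.append(
            (g, ga.degree(g) if in_a else 0, gb.degree(g) if in_b else 0, in_a, in_b)
        )
    return pd.DataFrame(
        rows, columns=["gene", "degree_A", "degree_B", "present_A", "present_B"]
    )


def select_connectivity_extremes(
    g: nx.Graph,
    cov: CovariationMatrix,
    n_top: int,
    n_isolated: int,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Top-connected genes of the graph vs random genes isolated at threshold.

    The top list ranks by degree, with ties broken by strength and then
    gene id; the isolated list samples uniformly without replacement from
    the genes present in the covariation matrix but absent from the graph
    (i.e. isolated at the construction threshold).
    """
    deg = dict(g.degree())
    strength = dict(g.degree(weight="weight"))
    ranked = sorted(deg, key=lambda u: (-deg[u], -strength[u], str(u)))
    if n_top > len(ranked):
        raise ValueError("n_top exceeds the number of connected genes")
    top = [str(u) for u in ranked[:n_top]]

    isolated = sorted(set(cov.gene_ids) - set(map(str, g.nodes())))
    if len(isolated) < n_isolated:
        raise ValueError(
            f"only {len(isolated)} isolated genes available, need {n_isolated}"
        )
    rng = stream(seed, "select_connectivity_extremes")
    pick = rng.choice(len(isolated), size=n_isolated, replace=False)
    return top, [isolated[i] for i in sorted(pick)]


@dataclass
class CVProfile:
    """Per-gene abundance mean/CV and per-bin median CVs for two gene groups."""

    per_gene: pd.DataFrame = field(repr=False)
    per_bin: pd.DataFrame = field(repr=False)
    mean_ratio: float = float("nan")


def cv_by_abundance(
    abundance: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_bins: int = 10,
    min_mean: float | None = None,
) -> CVProfile:
    """Coefficient of variation across tissues, binned by mean abundance.

    Each gene's CV is sd/mean across the tissue columns (sample sd, n-1
    denominator).  Genes of both groups are pooled, ranked by mean
    abundance, and cut into ``n_bins`` equal-count bins; the median CV of
    each group within each bin and their ratio (B over A) are reported,
    along with the average ratio across bins.  ``min_mean`` optionally
    floors the genes considered.
    """
    if abundance.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    sel: list[tuple[str, str]] = [(g, "A") for g in group_a] + [
        (g, "B") for g in group_b
    ]
    rows = []
    dropped = 0
    for gene, grp in sel:
        if gene not in abundance.index:
            continue
        vals = abundance.loc[gene].to_numpy(dtype=float)
        mean = vals.mean()
        if mean == 0:
            dropped += 1
            continue
        if min_mean is not None and mean < min_mean:
            continue
        rows.append((gene, grp, mean, vals.std(ddof=1) / mean))
    if dropped:
        warnings.warn(f"dropped {dropped} zero-mean gene(s)", stacklevel=2)
    per_gene = pd.DataFrame(rows, columns=["gene", "group", "mean", "cv"])
    for grp in ("A", "B"):
        if (per_gene["group"] == grp).sum() < n_bins:
            raise ValueError(f"fewer than n_bins={n_bins} usable genes in group {grp}")

    per_gene["bin"] = pd.qcut(per_gene["mean"].rank(method="first"), n_bins,
                              labels=False)
    med = per_gene.groupby(["bin", "group"], observed=True)["cv"].median().unstack()
    per_bin = pd.DataFrame(
        {
            "bin": med.index,
            "median_cv_A": med.get("A"),
            "median_cv_B": med.get("B"),
        }
    ).reset_index(drop=True)
    per_bin["ratio_B_over_A"] = per_bin["median_cv_B"] / per_bin["median_cv_A"]
    mean_ratio = float(per_bin["ratio_B_over_A"].mean(skipna=True))
    return CVProfile(per_gene, per_bin, mean_ratio)
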