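"""Proportionality scores between gene TE profiles and matrix comparisons.

The covariation score between two genes is the proportionality statistic

    rho_ij = 1 - var(x_i - x_j) / (var(x_i) + var(x_j)),

computed on log-transformed TE profiles x = log(TE).  rho lies in [-1, 1]:
it is 1 when the two log-profiles differ by a constant (perfect
proportionality on the raw scale), -1 when one is the negation of the
other up to a constant, and near 0 for unrelated profiles.  Because only
variances of rows and row differences enter, rho is invariant to scaling
a TE profile by a positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrices import CovariationMatrix, TEMatrix

__all__ = [
    "rho_proportionality",
    "absolute_scores",
    "pairwise_difference",
    "DifferenceSummary",
]

_LOG_FUNCS = {"e": np.log, "2": np.log2, "10": np.log10}


def rho_proportionality(te: TEMatrix, log_base: str = "e") -> CovariationMatrix:
    """Pairwise proportionality rho between all gene TE profiles.

    Genes whose log-profile has zero variance across samples (rho is
    undefined for every pair involving them) are dropped with a warning.
    Note rho itself is independent of the log base, since the base change
    rescales every variance by the same constant.
    """
    if log_base not in _LOG_FUNCS:
        raise ValueError(f"log_base must be one of {sorted(_LOG_FUNCS)}")
    if te.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate rho")
    x = _LOG_FUNCS[log_base](te.values)

    var = x.var(axis=1, ddof=1)
    keep = var > 0
    if not np.all(keep):
        dropped = [g for g, k in zip(te.gene_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s): {dropped[:5]}...",
            stacklevel=2,
        )
        x, var = x[keep], var[keep]
    genes = [g for g, k in zip(te.gene_ids, keep) if k]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with positive variance")

    # var(x_i - x_j) = var_i + var_j - 2 cov_ij  =>  rho = 2 cov / (var_i + var_j)
    cov = np.cov(x, ddof=1)
    denom = var[:, None] + var[None, :]
    rho = 2.0 * cov / denom
    rho = np.clip(rho, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return CovariationMatrix(genes, rho)


def absolute_scores(cov: CovariationMatrix) -> CovariationMatrix:
    """Element-wise absolute value of the scores (diagonal unchanged)."""
    return CovariationMatrix(list(cov.gene_ids), np.abs(cov.scores))


@dataclass
class DifferenceSummary:
    """Pairwise |score difference| between two matrices on their shared genes."""

    gene_ids: list[str]
    abs_differences: np.ndarray = field(repr=False)
    exceedance: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.exceedance.values()):
            raise ValueError("exceedance fractions must lie in [0, 1]")


def pairwise_difference(
    cov_a: CovariationMatrix,
    cov_b: CovariationMatrix,
    thresholds: Sequence[float] = (0.25, 0.5),
) -> DifferenceSummary:
    """|Delta score| over the upper triangle of the shared-gene submatrices.

    For each requested threshold t the summary reports the fraction of
    gene pairs with |score_A - score_B| > t (strict exceedance), which is
    non-increasing in t by construction.
    """
    shared = cov_a.overlap(cov_b)
    if len(shared) < 2:
        raise ValueError("need at least 2 overlapping genes")
    sub_a = cov_a.subset(shared).scores
    sub_b = cov_b.subset(shared).scores
    iu = np.triu_indices(len(shared), k=1)
    diffs = np.abs(sub_a[iu] - sub_b[iu])
    exceedance = {float(t): float(np.mean(diffs > t)) for t in thresholds}
    return DifferenceSummary(shared, diffs, exceedance)
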