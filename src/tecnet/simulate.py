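"""Synthetic translation-efficiency and covariation data with planted structure.

The generators here stand in for curated ribosome-profiling repositories:
they produce gene x sample TE matrices whose pairwise proportionality
(rho) is analytically controlled, paired covariation matrices sharing only
part of their module structure, and i.i.d. degree samples from the
distributions used to stress-test the scale-free machinery.

The TE model is a latent factor on the log scale: gene *i* in module *b*
has ``log TE = mu_i + a_i * f_b + background_sd * eps``, with the loading
``a_i`` solved so that the expected rho between two module members equals
the requested within-module strength (rho between genes sharing a factor
with loading *a* and noise s.d. *s* is exactly ``a**2 / (a**2 + s**2)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rng import stream
from .matrices import CovariationMatrix, TEMatrix

__all__ = [
    "PlantedStructure",
    "simulate_te_matrix",
    "simulate_covariation_pair",
    "sample_degree_counts",
]


@dataclass
class PlantedStructure:
    """Module/hub layout planted into a simulated TE matrix.

    Parameters
    ----------
    block_assignments:
        Map from gene index to module id; genes not listed are background.
    within_strength:
        Target |rho| between two genes of the same module, in [0, 1].
    background_sd:
        Standard deviation of per-gene log-scale noise.
    hub_spec:
        Optional list of ``(gene_index, n_partners)`` pairs.  Each hub is
        wired to that many background genes through a hub-specific factor;
        hub-partner rho targets ``within_strength`` while partner-partner
        rho is held at the lower cross-strength ``w**2 + 0.3*w*(1-w)`` so a
        threshold between the two separates the star from the clique.
    seed:
        Integer seed; fixed seed gives bitwise-reproducible output.
    """

    block_assignments: Mapping[int, int] = field(default_factory=dict)
    within_strength: float = 0.9
    background_sd: float = 1.0
    hub_spec: list[tuple[int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_strength <= 1.0:
            raise ValueError("within_strength must lie in [0, 1]")
        if self.background_sd < 0:
            raise ValueError("background_sd must be non-negative")
        sizes: dict[int, int] = {}
        for b in self.block_assignments.values():
            sizes[b] = sizes.get(b, 0) + 1
        if any(s < 2 for s in sizes.values()):
            raise ValueError("every planted block needs at least 2 genes")

    @classmethod
    def from_block_sizes(
        cls,
        sizes: Sequence[int],
        within_strength: float = 0.9,
        background_sd: float = 1.0,
        hub_spec: list[tuple[int, int]] | None = None,
        seed: int = 0,
    ) -> "PlantedStructure":
        """Assign the first ``sum(sizes)`` gene indices to consecutive blocks."""
        assignments: dict[int, int] = {}
        i = 0
        for b, size in enumerate(sizes):
            for _ in range(size):
                assignments[i] = b
                i += 1
        return cls(assignments, within_strength, background_sd, hub_spec, seed)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_te_matrix(
    n_genes: int, n_samples: int, structure: PlantedStructure
) -> TEMatrix:
    """Simulate a strictly positive TE matrix with planted covarying modules."""
    if n_genes <= 0 or n_samples <= 0:
        raise ValueError("n_genes and n_samples must be positive")
    if n_samples < 3:
        raise ValueError("need at least 3 samples for downstream proportionality")
    if structure.block_assignments and max(structure.block_assignments) >= n_genes:
        raise ValueError("planted block gene index exceeds n_genes")

    rng = stream(structure.seed, "simulate_te_matrix")
    w = structure.within_strength
    s = structure.background_sd

    # per-gene baseline and noise on the log scale
    mu = rng.normal(0.0, 1.0, size=n_genes)
    log_te = mu[:, None] + s * rng.normal(size=(n_genes, n_samples))

    if s == 0.0 or w >= 1.0:
        loading = 1.0
    else:
        loading = s * math.sqrt(w / (1.0 - w))

    block_ids = sorted(set(structure.block_assignments.values()))
    factors = {b: rng.normal(size=n_samples) for b in block_ids}
    for gene, b in structure.block_assignments.items():
        log_te[gene] += loading * factors[b]

    if structure.hub_spec:
        in_module = set(structure.block_assignments)
        background = [i for i in range(n_genes) if i not in in_module]
        for hub, n_partners in structure.hub_spec:
            if hub in in_module:
                raise ValueError("hub genes must be background genes")
            candidates = [g for g in background if g != hub]
            if n_partners > len(candidates):
                raise ValueError("not enough background genes for hub partners")
            partners = rng.choice(candidates, size=n_partners, replace=False)
            f_hub = rng.normal(size=n_samples)
            w2 = w * w + 0.3 * w * (1.0 - w)  # partner-partner cross strength
            # hub: loading 1, no idiosyncratic noise -> replace its noise row
            log_te[hub] = mu[hub] + f_hub
            if w > 0:
                t = w2 * (1.0 - math.sqrt(max(0.0, 1.0 - w * w / w2))) / w
                s_p = t * math.sqrt((1.0 - w2) / w2) if w2 < 1 else 0.0
                for p in partners:
                    log_te[p] = (
                        mu[p] + t * f_hub + s_p * rng.normal(size=n_samples)
                    )
                    background.remove(int(p))

    return TEMatrix(_gene_names(n_genes), [f"S{j:04d}" for j in range(n_samples)],
                    np.exp(log_te))


def _planted_matrix(
    n_genes: int,
    blocks: Sequence[Sequence[int]],
    within_strength: float,
    background_sd: float,
    jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a covariation matrix directly: block value + jitter, clipped."""
    flat: set[int] = set()
    for block in blocks:
        bset = set(int(i) for i in block)
        if len(bset) != len(block):
            raise ValueError("duplicate gene inside a block")
        if flat & bset:
            raise ValueError("blocks overlap within one matrix")
        if max(bset, default=-1) >= n_genes:
            raise ValueError("block gene index exceeds n_genes")
        flat |= bset

    scores = np.zeros((n_genes, n_genes))
    iu = np.triu_indices(n_genes, k=1)
    scores[iu] = rng.normal(0.0, background_sd, size=iu[0].size) if background_sd > 0 else 0.0
    for block in blocks:
        idx = np.asarray(sorted(int(i) for i in block))
        for a_pos, a in enumerate(idx):
            for b in idx[a_pos + 1:]:
                scores[a, b] = within_strength + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
    scores = np.clip(scores, -1.0, 1.0)
    scores = scores + scores.T
    np.fill_diagonal(scores, 1.0)
    return scores


def simulate_covariation_pair(
    n_genes: int,
    shared_blocks: Sequence[Sequence[int]],
    specific_blocks_a: Sequence[Sequence[int]],
    specific_blocks_b: Sequence[Sequence[int]],
    within_strength: float,
    seed: int,
    background_sd: float = 0.02,
    jitter: float = 0.02,
) -> tuple[CovariationMatrix, CovariationMatrix]:
    """Draw two covariation matrices that share only part of their structure.

    Shared blocks receive scores near ``within_strength`` in both matrices;
    each specific block only in its own matrix.  Background entries are
    small-noise draws near zero.  Both outputs are exactly symmetric with
    unit diagonal and all values in [-1, 1].
    """
    if n_genes <= 1:
        raise ValueError("need at least 2 genes")
    rng_a = stream(seed, "simulate_covariation_pair/A")
    rng_b = stream(seed, "simulate_covariation_pair/B")
    genes = _gene_names(n_genes)
    scores_a = _planted_matrix(
        n_genes, list(shared_blocks) + list(specific_blocks_a),
        within_strength, background_sd, jitter, rng_a)
    scores_b = _planted_matrix(
        n_genes, list(shared_blocks) + list(specific_blocks_b),
        within_strength, background_sd, jitter, rng_b)
    return CovariationMatrix(genes, scores_a), CovariationMatrix(genes, scores_b)


def _sample_power_law(alpha: float, kmin: int, n: int, rng: np.random.Generator) -> np.ndarray:
    from .scalefree import sample_discrete_power_law

    return sample_discrete_power_law(alpha, kmin, n, rng)


def sample_degree_counts(
    dist: str,
    params: Mapping[str, float],
    n: int,
    kmin: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` i.i.d. integer degrees >= kmin from a named distribution.

    Supported distributions (all discrete, supported on integers >= kmin):

    - ``power_law``: p(k) ∝ k**-alpha (params: alpha > 1)
    - ``lognormal``: round of a continuous log-normal, rejected below kmin
      (params: mu, sigma)
    - ``exponential``: p(k) ∝ exp(-lam*k), i.e. a shifted geometric
      (params: lam > 0)
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    rng = stream(seed, f"sample_degree_counts/{dist}")
    if n == 0:
        return np.empty(0, dtype=int)

    if dist == "power_law":
        alpha = float(params["alpha"])
        if alpha <= 1.0:
            raise ValueError("power law requires alpha > 1 (normalizable)")
        return _sample_power_law(alpha, kmin, n, rng)
    if dist == "lognormal":
        mu, sigma = float(params["mu"]), float(params["sigma"])
        out: list[np.ndarray] = []
        remaining = n
        while remaining > 0:
            draw = np.rint(rng.lognormal(mu, sigma, size=max(2 * remaining, 100)))
            draw = draw[draw >= kmin].astype(int)
            out.append(draw[:remaining])
            remaining -= len(draw[:remaining])
        return np.concatenate(out)
    if dist == "exponential":
        lam = float(params["lam"])
        if lam <= 0:
            raise ValueError("exponential requires lam > 0")
        p = 1.0 - math.exp(-lam)
        return kmin - 1 + rng.geometric(p, size=n)
    raise ValueError(f"unknown distribution {dist!r}")
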