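"""End-to-end report bundles: characterize one network, compare two.

``run_characterize`` takes a covariation matrix and emits the tables
underlying a full topological characterization — threshold sweep, degree
distribution, scale-free report, clustering against the expected-degree
null, rich-club curve, and path-length histogram — plus a JSON manifest
recording every parameter, seed, and input hash needed to re-execute the
run bit-identically.

``run_compare`` takes two covariation matrices, builds both networks at
a common threshold, and emits the overlap/Jaccard/centrality-imbalance
and pairwise score-difference tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import stream
from .covariation import pairwise_difference
from .compare import centrality_imbalance, neighborhood_jaccard
from .graphs import (
    DEFAULT_GRID,
    build_network,
    graph_summary,
    largest_component,
    select_threshold,
    sweep_thresholds,
    write_edgelist,
)
from .matrices import CovariationMatrix
from .nullmodels import expected_degree_graph
from .scalefree import (
    compare_alternatives,
    fit_power_law,
    loglog_degree_r2,
    plausibility_pfit,
)
from .topology import (
    clustering_coefficients,
    path_length_distribution,
    rich_club_curve,
)

__all__ = ["RunConfig", "run_characterize", "run_compare"]


@dataclass
class RunConfig:
    """Parameters of a pipeline run; everything lands in the manifest."""

    input_path: str
    input_path_b: str | None = None
    threshold: float | str = "auto"
    mode: str = "weighted"
    grid: list[float] = field(default_factory=lambda: list(DEFAULT_GRID))
    n_null: int = 50
    n_boot: int = 1000
    diff_thresholds: list[float] = field(default_factory=lambda: [0.1, 0.25, 0.5])
    seed: int = 0
    outdir: str = "tecnet_out"


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, extra: dict) -> None:
    manifest = {
        "tecnet_version": __version__,
        "config": asdict(config),
        "inputs": {
            p: _sha256(p)
            for p in (config.input_path, config.input_path_b)
            if p is not None
        },
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _resolve_threshold(cov: CovariationMatrix, config: RunConfig):
    sweep = sweep_thresholds(cov, config.grid)
    if config.threshold == "auto":
        threshold = select_threshold(sweep)
    else:
        threshold = float(config.threshold)
    return sweep, threshold


def run_characterize(config: RunConfig) -> dict:
    """Characterize one covariation network; write tables + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov = CovariationMatrix.read(config.input_path)

    sweep, threshold = _resolve_threshold(cov, config)
    sweep.to_frame().to_csv(outdir / "threshold_sweep.tsv", sep="\t", index=False)

    g = build_network(cov, threshold, mode=config.mode, drop_isolated=True)
    summary = graph_summary(g)
    write_edgelist(g, outdir / "network_edges.tsv")

    degrees = np.array([d for _, d in g.degree()], dtype=int)
    uniq, counts = np.unique(degrees, return_counts=True)
    pd.DataFrame({"degree": uniq, "count": counts, "p": counts / degrees.size}).to_csv(
        outdir / "degree_distribution.tsv", sep="\t", index=False
    )

    # tiny or near-regular networks cannot support a tail analysis; the
    # report then records the reason instead of aborting the run
    try:
        fit = fit_power_law(degrees)
        plaus = plausibility_pfit(
            degrees, fit, n_boot=config.n_boot,
            seed=int(stream(config.seed, "pfit_seed").integers(2**31)),
        )
        alts = compare_alternatives(degrees, fit)
        scalefree_report = {
            "alpha": fit.alpha,
            "kmin_star": fit.kmin_star,
            "ks_D": fit.ks_D,
            "ntail": fit.ntail,
            "pfit": plaus.pfit,
            "n_boot": plaus.n_boot,
            "power_law_rejected": plaus.reject,
            "alternatives": [
                {
                    "alternative": a.alternative,
                    "log_likelihood_ratio": a.log_likelihood_ratio,
                    "p_value": a.p_value,
                    "fitted_params": a.fitted_params,
                    "converged": a.converged,
                }
                for a in alts
            ],
        }
    except ValueError as err:
        scalefree_report = {"skipped": str(err)}
    try:
        scalefree_report["loglog_r2"] = loglog_degree_r2(degrees)
    except ValueError as err:
        scalefree_report["loglog_r2"] = None
        scalefree_report.setdefault("skipped", str(err))
    (outdir / "scalefree_report.json").write_text(
        json.dumps(scalefree_report, indent=2)
    )

    # clustering vs expected-degree null
    clust = clustering_coefficients(g, weighted=False)
    clust.to_csv(outdir / "clustering.tsv", sep="\t", index=False)
    null_rng = stream(config.seed, "clustering_null")
    null_means = []
    for _ in range(max(1, config.n_null // 5)):
        null = expected_degree_graph(degrees.tolist(),
                                     seed=int(null_rng.integers(2**31)))
        null_means.append(clustering_coefficients(null)["clustering"].mean())
    pd.DataFrame(
        {
            "statistic": ["observed_mean_clustering", "null_mean_clustering"],
            "value": [clust["clustering"].mean(), float(np.mean(null_means))],
        }
    ).to_csv(outdir / "clustering_vs_null.tsv", sep="\t", index=False)

    rc = rich_club_curve(g, n_null=config.n_null, seed=config.seed)
    rc.table.to_csv(outdir / "rich_club.tsv", sep="\t", index=False)

    lcc = largest_component(g)
    paths = path_length_distribution(lcc)
    pd.DataFrame(
        {"length": list(paths.histogram), "pairs": list(paths.histogram.values())}
    ).to_csv(outdir / "path_lengths.tsv", sep="\t", index=False)

    result = {
        "threshold": threshold,
        "n_nodes": summary.n,
        "n_edges": summary.m,
        "density": summary.density,
        "largest_component": lcc.number_of_nodes(),
        "mean_path_length": paths.mean,
        "scalefree": scalefree_report,
    }
    _write_manifest(config, outdir, {"result": result})
    return result


def run_compare(config: RunConfig) -> dict:
    """Compare two covariation networks; write tables + manifest."""
    if config.input_path_b is None:
        raise ValueError("run_compare needs two input matrices")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov_a = CovariationMatrix.read(config.input_path)
    cov_b = CovariationMatrix.read(config.input_path_b)

    if config.threshold == "auto":
        threshold = select_threshold(sweep_thresholds(cov_a, config.grid))
    else:
        threshold = float(config.threshold)

    ga = build_network(cov_a, threshold, mode=config.mode, drop_isolated=True)
    gb = build_network(cov_b, threshold, mode=config.mode, drop_isolated=True)

    jac = neighborhood_jaccard(ga, gb)
    jac.to_csv(outdir / "jaccard.tsv", sep="\t", index=False)

    imbalances = {}
    for measure in ("strength", "closeness", "betweenness"):
        tab = centrality_imbalance(ga, gb, measure)
        tab.to_csv(outdir / f"imbalance_{measure}.tsv", sep="\t", index=False)
        imbalances[measure] = tab

    diff = pairwise_difference(cov_a, cov_b, config.diff_thresholds)
    pd.DataFrame(
        {
            "threshold": list(diff.exceedance),
            "fraction_exceeding": list(diff.exceedance.values()),
        }
    ).to_csv(outdir / "difference_exceedance.tsv", sep="\t", index=False)

    result = {
        "threshold": threshold,
        "n_nodes_A": ga.number_of_nodes(),
        "n_edges_A": ga.number_of_edges(),
        "n_nodes_B": gb.number_of_nodes(),
        "n_edges_B": gb.number_of_edges(),
        "n_overlapping": int(len(jac)),
        "median_jaccard": float(jac["jaccard"].median()) if len(jac) else float("nan"),
        "exceedance": {str(k): v for k, v in diff.exceedance.items()},
    }
    _write_manifest(config, outdir, {"result": result})
    return result
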