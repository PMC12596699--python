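# Methods

## Covariation scores

`rho_proportionality` computes, for natural-log-transformed TE profiles,
rho = 1 − var(x_i − x_j)/(var x_i + var x_j), vectorized through the
identity var(x_i − x_j) = var x_i + var x_j − 2 cov(x_i, x_j). Variances
use the unbiased (n−1) estimator; the choice cancels in the ratio as
long as it is consistent. No centering is applied (rho is shift-invariant
in log space, hence scale-invariant in raw space), and the log base is
irrelevant to the value since a base change rescales numerator and
denominator identically. Genes with zero variance across samples make
rho undefined for every pair involving them; they are dropped with a
warning rather than failing the whole matrix. Results are clipped to
[−1, 1] (the exact bound can be overshot by floating-point round-off),
exactly symmetrized, and given a unit diagonal.

The per-pair variance-of-log-ratio form above is one of the two common
conventions for this proportionality statistic (the other references
each profile to the sample's centered log-ratio). Exact reproduction of
externally produced matrices should be validated against their source
before mixing conventions.

## Network construction and threshold choice

An edge joins genes i and j when |rho_ij| ≥ t. The comparison is closed
(≥) by default with a `strict` switch, since either reading of "above
the threshold" is defensible; the two differ only for scores exactly at
t. The working threshold is the grid value maximizing the number of
multi-node connected components (components with ≥ 2 nodes, equal to
total components minus isolated nodes), with ties broken toward the
*largest* threshold — preferring the sparser of equally modular
networks. The default sweep grid is 0.50–0.95 in steps of 0.01.
Diagonal and non-finite entries never produce edges.

## Null models

Three calibrated references frame the observed topology (all via
networkx generators, which implement exactly these constructions):

- **Barabási–Albert**: star on m+1 nodes, then growth with m edges per
  node, attachment probability proportional to degree, target sampling
  without duplicate edges. Edge count is exactly m + (n−m−1)·m.
  Calibration: m = round(m_obs/n_obs), the edge-to-vertex ratio.
- **Watts–Strogatz**: ring lattice with k nearest neighbors, each edge
  rewired with probability 0.01 (default) avoiding self-loops and
  duplicates; edge count nk/2 for any rewiring probability.
  Calibration: k = mean degree rounded to the nearest even integer.
  When comparing to a specific component, n defaults to the component
  size (configurable).
- **Expected-degree (Chung–Lu)**: independent edges with
  p_uv = d_u·d_v/Σd, no self-loops. Note that excluding self-loops makes
  the exact mean degree d_u(Σd − d_u)/Σd, slightly below d_u for hubs;
  when max(d)² > Σd some probabilities clip at 1 and a warning is
  emitted.

## Scale-free analysis

The degree tail model is the **discrete** power law with Hurwitz-zeta
normalization, p(k) = k^(−α)/ζ(α, kmin) — degrees are integers and the
continuous approximation biases α at small kmin. For every candidate
kmin among the distinct observed degrees leaving at least `min_tail`
(default 10) tail observations, α is estimated by bounded scalar
maximization of the tail log-likelihood (α ∈ (1.001, 8], xatol 1e−5),
and the fit is scored by the Kolmogorov–Smirnov distance between the
empirical and fitted tail CDFs evaluated at **every integer** in
[kmin, max degree] — not only at observed values — so that model mass
on unobserved degrees is registered. The cutoff with minimal D wins;
ties go to the smaller cutoff. Fewer than 50 tail observations trigger
a warning.

**Sampling** from the fitted law uses exact inverse-CDF inversion of
the survival function over a 2^16-wide window, and the continuous-tail
inversion k = [u(α−1)ζ(α, kmin)]^(1/(1−α)) for draws beyond it, where
the discrete/continuous relative difference is O(1/k) and negligible.

**Plausibility (pfit)** follows the semiparametric hybrid bootstrap:
each of n_boot replicates draws n values from the fitted tail model
with probability ntail/n, otherwise uniformly from the observed
sub-kmin degrees; each replicate is refit with its own cutoff scan
(same candidate rule as the observed fit), and pfit is the fraction of
replicates with strictly larger D than observed. Rejection threshold
0.1. The default n_boot is 1000 for reproduction runs; tests use 200
for runtime.

**Alternatives** are fit on the same tail (k ≥ kmin*): the discrete
exponential (shifted geometric; closed-form MLE), the discretized
positive log-normal (μ ≥ 0, Nelder–Mead over (μ, log σ); the
normalization sums the pmf exactly over a head window and closes the
tail with the Gaussian integral), and the truncated power law
k^(−α)e^(−γk) (Nelder–Mead over (α, log γ); normalization by chunked
summation with a geometric tail bound). Non-nested comparisons use the
normalized Vuong statistic, p = erfc(|R|/√(2nσ²)); the truncated power
law nests the pure power law at γ = 0, so its p-value is a one-degree
chi-square on twice the likelihood gain. Positive ratios favor the
power law. Optimizer failures are reported per alternative, not fatal.

The descriptive log–log regression (OLS of log P(k) on log k over
distinct observed degrees) is kept for comparability with the
literature, but it is a weak instrument: single-count degrees in the
far tail form a noise floor that degrades R² for genuine power-law
samples as much as curvature does for exponential ones. The package's
tests therefore treat R² contrasts only in noiseless form and leave
model discrimination to the bootstrap and likelihood-ratio machinery.

## Topology metrics

Unweighted clustering follows the triangle-count formula; weighted
clustering uses the geometric mean of triangle weights after
normalizing by the graph-wide maximum weight (networkx's
implementation), which reduces exactly to the unweighted coefficient
when all weights are equal. Nodes of degree < 2 score 0 rather than
undefined, keeping distributions plottable.

Rich-club φ(k) is computed for every k from 0 to max degree − 1 as the
density among nodes of degree > k, flagged undefined (NaN) where fewer
than 2 such nodes exist, and normalized by the mean φ(k) of
expected-degree replicates generated from the observed degree sequence
(replicates use their own realized degrees).

Centralities: node strength is the sum of incident weights. Closeness
and betweenness are shortest-path based; similarity weights are turned
into distances by a configurable transform — `reciprocal` (1/w,
default: strong covariation = short hop), `one_minus`, or `raw`
(weights used directly as distances, the literal reading of
"shortest path distance by edge weights"). Closeness uses the
component-size correction (n_c−1)/(n−1); betweenness excludes endpoints
and normalizes by (n−1)(n−2)/2. Path-length distributions are computed
by unweighted BFS over the largest component.

## Comparison of two networks

"Overlapping genes" means genes that survive thresholding and
isolated-node removal in **both** networks. Jaccard, centrality
imbalance (A − B, ranked by magnitude), and per-gene degree shifts are
restricted to that set; exceedance fractions and edge-retention gaps
use strict inequality (fraction of pairs with difference strictly
greater than the threshold). The abundance/CV analysis computes
CV = sd/mean per gene across tissues (sample sd), pools both gene
groups before ranking by mean abundance into equal-count bins
(deciles by default), and reports per-bin median CVs and their ratio;
binning each group separately and equal-width bins are available
alternatives. Zero-mean genes are dropped with a warning; a mean
abundance floor is a parameter, not a constant.

## Communities

Louvain modularity optimization runs on edge weights, by convention on
the largest connected component, resolution 1.0, with a fixed seed —
with the caveat that the cluster count is seed-sensitive. Maximal
cliques use pivoting Bron–Kerbosch on the binarized graph (clique
membership is weight-agnostic).

## Synthetic data: what it emulates, and what it does not

`simulate_te_matrix` uses a latent factor on the log scale: gene i in
module b has log TE = μ_i + a·f_b + s·ε with μ_i ~ N(0,1),
f_b, ε ~ N(0,1), and loading a = s√(w/(1−w)) chosen so that the
expected rho between two module members is exactly
a²/(a²+s²) = w, the requested within-module strength. With s = 0 (or
w = 1) all module profiles are identical up to the shared factor and
rho = 1 exactly.

Hubs cannot be star-shaped under a single shared factor (hub–partner
rho can never exceed partner–partner rho within one factor), so each
hub gets its own factor with zero idiosyncratic noise while its
partners' loadings and noise solve rho(hub, partner) = w and
rho(partner, partner) = w₂ = w² + 0.3·w(1−w) (feasibility requires
w₂ ≥ w²); thresholding between w₂ and w then isolates the star.

`simulate_covariation_pair` draws score matrices directly — block
entries at the target strength plus small jitter, background entries
near zero, clipped, symmetrized — which is faster when the TE stage is
not under test. Default background sd and jitter are 0.02, far below
any sensible threshold, so planted blocks map exactly onto thresholded
components.

These generators emulate the *structure* relevant to the pipeline —
symmetric score matrices in [−1,1] with planted modules, hubs, and
partially shared structure between paired matrices — not the marginal
distributions of real ribosome-profiling data: no compositional
coupling between genes, no sample-depth or batch effects, no realistic
mRNA abundance distributions, and modules are exchangeable blocks
rather than biological pathways. Passing tests therefore establish the
correctness of the graph-theoretic and statistical machinery on
controlled inputs, not the biological findings obtainable from any
particular real dataset.

## Test problem sizes and study conditions

- Power-law exponent recovery: α ∈ {2.1, 2.5, 3.0}, 10^5 tail samples,
  tolerance ±0.05.
- pfit calibration: 20 runs of true power laws (α = 2.5, n = 2000,
  n_boot = 200); the rejection rate at the 0.1 cutoff must lie in
  [0.02, 0.25].
- pfit power: 10 runs of a heavy-curvature log-normal. The condition is
  μ = 2.5, σ = 0.3, n = 10000: at n ≈ 4000 the cutoff scan routinely
  escapes into a small conforming tail and the test rejects only about
  half the time — a documented weakness of the KS-bootstrap approach
  against log-normals — whereas at n = 10000 with this curvature the
  rejection is consistent.
- BA log–log R² reference (n = 3804, m = 7): averaged over 50 seeds
  because ~7% of seeds produce an extreme hub that drags R² far below
  the typical value (per-seed sd ≈ 0.045, median 0.848).
- Oracle equivalences run on random graphs with n ≤ 30 (exhaustive
  clique enumeration n ≤ 12).

## Known limitations

- The pfit bootstrap has limited power against log-normal alternatives
  at moderate n; report the likelihood-ratio comparisons alongside it.
- The truncated power-law normalization uses a geometric tail bound for
  extremely small γ; fitted γ below ~1e−6 should be read as "no
  detectable truncation".
- Louvain cluster counts (not quality) vary across seeds; treat the
  partition, not the count, as the result.
- Expected-degree nulls undershoot hub degrees when max(d)² > Σd; the
  rich-club normalization inherits this conservative bias.
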