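# Methods

This note records the models, conventions, and numerical choices behind
`mesoresolve`, in enough detail to reimplement it.

## Quality functions and optimization

Binary modularity is Q = (1/2m) Σ_ij [B_ij − γ k_i k_j / 2m] δ(g_i, g_j)
with m the edge count; the weighted form replaces B by the weight matrix,
degrees by strengths, and m by the total edge weight, which makes Q^w
invariant under uniform rescaling of all weights.  The Newman–Girvan null
term carries the structural resolution γ ≥ 0: γ = 0 rewards any merge (a
connected network collapses to one community), and above
γ* = max_ij 2m w_ij / (s_i s_j) (exposed as `singleton_gamma`) no pairwise
merge has positive gain, so the optimum is all singletons.  Sweeping γ
between these limits traces community structure from coarse to fine.

Optimization is Louvain-style: repeated passes of single-node moves over a
seeded random node order, followed by aggregation of communities into
super-nodes (self-loop weights preserved), until no move improves Q.  Two
deliberate choices:

* **Move selection is random-improving, not best-move.**  Each visited node
  moves to a community drawn uniformly among the strictly improving
  candidates (neighboring communities, plus an empty community when leaving
  the current one is itself an improvement).  Exhaustive enumeration of all
  visit orders on small counterexamples shows best-move dynamics can be
  unable to reach the global optimum from *any* order, whereas
  random-improving selection reaches it across restarts; on 8-node graphs,
  20 restarts match brute-force partition enumeration (Bell-number search)
  at every tested γ.  The cost is roughly 2–3× more move evaluations per
  run.
* **Ties keep the node in place**, guaranteeing termination; the reported Q
  is always recomputed from the returned partition with the exact quality
  function, so optimizer bookkeeping cannot drift from the definition
  (self-consistency asserted to 1e-12 in the tests).

Because near-optimal partitions are plentiful and nearly degenerate, every
community-based diagnostic is reported as mean ± SD over independent
restarts (default 20).  On the synthetic ensembles, this optimization
scatter is small compared to realization-to-realization scatter, which is
what justifies averaging.  Partitions are not consensus-merged; laterality
and radius are computed per restart and averaged the same way.
Disconnected inputs are allowed — components never merge profitably at
γ > 0 — and are not an error.

## Thresholding conventions

Weights are max-normalized (w ← w / w_max, idempotent, order-preserving)
before soft thresholding so that w^r stays in [0, 1].  Soft thresholding
never changes the edge set; as r → 0 all edges approach weight 1
(equivalent to a hard threshold at zero), and as r → ∞ only the maximal
weights survive at scale 1 (a hard threshold just below w_max) — with the
caveat that "large r" must be large relative to the number of edges when
the weight distribution is continuous, since the relevant scale is the gap
between the top order statistics.

Windowed thresholding is defined on **ascending weight ranks**, not raw
weights: the percentile of rank i (1-based, i = 1..M) is (i − 0.5)/M, a
window retains a contiguous block of round(s·M) ranks (round = half away
from zero, minimum 1), and the block is placed so its mean percentile is
closest to the requested W̄ (ties toward lower ranks; placement clipped to
[1, M]).  The feasible W̄ range is [s/2, 1 − s/2].  Ties in weight are
broken by stable lexicographic (i, j) pair order, so every (s, W̄) selects
a unique, reproducible edge set even on models whose weights are discrete
by construction.  An alternate symmetric matrix (e.g. inter-node distance)
may supply the ranking while the network supplies the edge support.  Rank
windows hold density exactly constant across the family; a raw-weight-scale
window would not.

One visible consequence of tie-breaking: when a window lies strictly inside
a tied weight level, the retained sub-block is a deterministic slice in pair
order, so windowed curves show small systematic within-plateau variation
(a few percent of the curve range) rather than pure noise.  Shape tests
therefore compare plateau means and bound pointwise dips at 10% of the
curve range.

## Mesoscale diagnostics

**Bipartivity** uses the symmetric eigendecomposition of the *binary*
adjacency; β = Σ cosh λ_j / Σ exp λ_j, evaluated with the spectrum shifted
by λ_max so dense graphs cannot overflow (λ_max grows with degree).  A
weighted β is out of scope; windowed binary graphs are the intended input.
The two-group split takes the eigenvector of the smallest eigenvalue of
A − γ k kᵀ/2m (γ = 1 by default); entries ≥ 0 (including exact zeros) form
group one, the eigenvector sign is canonicalized on its first nonzero
entry, and a degenerate smallest eigenvalue falls back to the first
eigenvector with a logged warning.

**Laterality** Λ_c = |N_L,c − N_R,c| / N_c per community; the partition
value (1/N) Σ_c N_c Λ_c is biased upward by fragmentation (singletons score
1 by definition), so the expectation under uniform permutation of the
category label vector — category totals fixed — is subtracted.  The null is
estimated from exactly `n_random` seeded draws (default 1000) and the
empirical Monte-Carlo standard error is reported alongside.

**Community radius** uses the *population* (divide-by-N_c) standard
deviation along each coordinate axis, making the two-node case symmetric
(ρ = half the separation) and singletons exactly 0; ρ̄ = Σ_c N_c ρ_c /
(N ρ_net) is normalized by the whole-node-set radius so a single all-node
community scores exactly 1.

## Rewiring probe

`rewire_fraction` selects round(f·M) edges by weight rank from the chosen
end (ties in stable pair order) and sequentially reassigns each edge's
weight to a uniformly random currently-empty pair (no self-loops or
multi-edges; earlier re-placements block reuse).  Node count, edge count,
and the weight multiset are preserved; the degree sequence deliberately is
not — this uniform re-placement is the reading under which an
Erdős–Rényi network is statistically invariant under rewiring, which is the
probe's calibration property.  A degree-preserving double-edge-swap variant
is available behind `preserve_degrees=True` for sensitivity analysis.
A complete graph admits no rewiring and is returned unchanged with a
warning.

## Synthetic benchmark models

All four generators emit weighted networks in which weight rank encodes the
structural feature the model isolates; none is a biological model.  Exact
weight values for the clustered models are design choices (the structure
lives in the rank order, and the bands are configurable):

* **ER** — n_edges pairs uniform without replacement, weights i.i.d.
  uniform on (0, 1] (open at 0 so every edge remains an edge).
* **RL** — shells of topological distance filled outward, in increasing
  start-index order within a shell; weight w(d) = 1 − (d − 1)/d_used, so
  nearest neighbours weigh 1 and the farthest used shell 1/d_used > 0.
  Deterministic; a budget below n_edges < n_nodes leaves the ring
  incomplete (logged, not an error).
* **SW** — consecutive fully connected clusters on the smallest dyadic
  count 2^j·cluster_size ≥ N, surplus nodes deleted at random with their
  edges, remaining budget placed uniformly between clusters.  Intra-cluster
  weights uniform on [0.6, 1.0], inter-cluster on (0, 0.4]: disjoint bands,
  so the top-band window reproduces the disjoint-clique graph exactly.
  A budget below the intra-cluster count subsamples intra edges (logged).
* **FH** — complete elementary groups (weight 1) joined pairwise level by
  level on the dyadic base; at level l ≥ 2, eligible cross pairs receive
  edges independently with probability p_l = p₂ σ^(2−l) and weight
  2^(1−l).  σ defaults to 2 (density halves per level while eligible pairs
  double, so each level contributes a roughly equal edge count — the
  configuration in which a fixed-size window can resolve every level);
  p₂ is solved so the *expected* edge count after surplus-node deletion
  equals the budget, and an infeasible budget (p₂ > 1) raises with the
  maximal feasible count.  The FH edge count is therefore stochastic;
  ER/RL/SW hit their budgets exactly.

Ensembles draw per-realization edge counts from a Gaussian (rounded,
clipped to [N − 1, N(N−1)/2]) with per-realization seeds spawned from the
master seed.  Two fixture generators support the spatial and group
analyses: `generate_embedded_modular` attaches disjoint Gaussian coordinate
clouds (SD 1 on a centroid ring of radius 20) and alternating binary
categories to an SW-style network; `generate_two_group_ensembles` produces
two SW ensembles identical except for an upward shift of group B's
intra-cluster weight band (shift 0 ⇒ exchangeable groups).

What these fixtures do *not* emulate: measurement noise, distance-dependent
connection probabilities, degree heterogeneity of real connectomes, or any
subject-level covariates.  Passing shape tests therefore validates the
machinery (thresholding, optimization, diagnostics, inference), not claims
about empirical brain data.

## MRF sweeps and group comparison

Sweeps report mean and SD per grid point with the sample count, and are
bit-reproducible under a master seed.  Default grids: soft-threshold powers
log-spaced on [1e-2, 1e2] (r = 1, the conventional single-point statistic,
is inserted if absent and the curve's argmax r_peak is exposed);
resolutions log-spaced on [2⁻⁴, 2⁶]; window positions evenly spaced over
the feasible W̄ range.  The soft-threshold sweep uses one optimizer seed
for the whole grid (common random numbers), so a network with tied weights
yields an exactly constant curve.  The joint W̄ × γ map reports mean
non-singleton community counts with a companion total-count matrix.

Group comparison: the pointwise statistic is the difference of group means
at each grid point; the curve-level statistic is the mean over the grid of
the absolute pointwise difference (a max-statistic variant is available).
The null permutes subject-to-group labels; p-values use the add-one
estimator (1 + #{null ≥ observed})/(n_perm + 1), which is valid and
slightly conservative.  Pointwise p-values are reported raw (the sweep is a
profile, not a family of confirmatory tests); an optional
Benjamini–Hochberg helper is provided but not applied by default.

## Problem sizes in the tests and acceptance script

Benchmark-shape checks use N = 256 with 20 model realizations and 3
optimizer restarts per windowed graph (realization averaging dominates the
restart noise at this size): FH with 3 levels (group 64, M = 24192,
~equal level fractions so the 25% window resolves each level; plateau
count = maximal runs of consecutive rises above 15% of the curve range,
plus one), ER at matched density, SW with clusters of 16 at M = 4800
(intra band = top 40% of edges).  The rewiring probe uses M = 3000 at
f = 10% with 20 rewiring realizations per order.  Permutation-test
calibration runs 500 null trials of fresh 29 + 29 ensembles of N = 32
small-world networks with 3-point Q^w(γ) curves at n_perm = 99, and 60
trials for power at an intra-band shift of 0.8.  The acceptance script
repeats the same computations at moderately reduced realization/trial
counts; every number it writes is computed at run time from the seed it is
given.

## Known limitations

* Louvain restarts guarantee the exhaustive optimum only on small graphs;
  on large networks the optimizer has the usual Louvain character of
  high-quality local optima.
* Laterality supports exactly two categories; no multi-category
  generalization.
* Bipartivity is defined for binary graphs only.
* The permutation test assumes exchangeable subjects under the null and a
  shared curve grid; no paired or covariate-adjusted designs.
* Statistical edge-significance thresholding (e.g. FDR on correlation
  matrices) is out of scope, as are neuroimaging file formats and
  parcellation handling.
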