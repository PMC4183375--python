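"""Mesoscopic response functions (MRFs) and group comparison.

An MRF is a curve of a network diagnostic versus a control parameter —
soft-threshold power ``r``, window mean percentile ``W̄``, structural
resolution ``γ``, or rewired fraction ``f``.  Where a conventional analysis
reports one number per network (e.g. Q at r = 1), the MRF exposes how the
diagnostic responds across the whole weight or resolution range, and two
groups of networks can be compared nonparametrically by permuting group
labels of their curves.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .community import (OptimizationResult, louvain_optimize,
                        partition_statistics)
from .mesoscale import bipartivity, community_laterality, community_radius
from .network import SpatialEmbedding, WeightedNetwork, normalize_weights
from .thresholding import ThresholdWindow, soft_threshold, window_grid, \
    windowed_threshold

__all__ = [
    "MRFCurve",
    "MRFMatrix",
    "GroupComparison",
    "mrf_soft",
    "mrf_windowed",
    "mrf_resolution",
    "mrf_weight_resolution_map",
    "permutation_group_test",
    "default_gamma_grid",
    "default_r_grid",
]

WINDOW_DIAGNOSTICS = (
    "Q_binary", "bipartivity", "laterality", "n_communities",
    "n_singletons", "n_nonsingleton",
)


def default_r_grid(n_points: int = 25) -> np.ndarray:
    """Log-spaced soft-threshold powers over [1e-2, 1e2]."""
    return np.logspace(-2, 2, n_points)


def default_gamma_grid(n_points: int = 25) -> np.ndarray:
    """Log-spaced structural resolutions over [2**-4, 2**6]."""
    return np.logspace(-4 * np.log10(2), 6 * np.log10(2), n_points)


@dataclass(frozen=True)
class MRFCurve:
    """A diagnostic sampled over an ascending control-parameter grid."""

    control_name: str
    grid: np.ndarray
    values: np.ndarray
    dispersion: np.ndarray
    n_samples: np.ndarray
    diagnostic_name: str = "diagnostic"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.size == 0:
            raise ValueError("curve grid must be nonempty")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("curve grid must be strictly ascending")
        values = np.asarray(self.values, dtype=float)
        dispersion = np.asarray(self.dispersion, dtype=float)
        n_samples = np.asarray(self.n_samples, dtype=int)
        if not grid.shape == values.shape == dispersion.shape == n_samples.shape:
            raise ValueError("grid/values/dispersion/n_samples lengths differ")
        for name, arr in (("grid", grid), ("values", values),
                          ("dispersion", dispersion), ("n_samples", n_samples)):
            arr = np.ascontiguousarray(arr)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def peak(self) -> tuple[float, float]:
        """(control value, diagnostic value) at the curve maximum."""
        idx = int(np.argmax(self.values))
        return float(self.grid[idx]), float(self.values[idx])

    def at(self, control_value: float) -> float:
        idx = np.flatnonzero(np.isclose(self.grid, control_value))
        if idx.size == 0:
            raise KeyError(f"{control_value} not on the curve grid")
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class MRFMatrix:
    """A diagnostic over a W̄ × γ grid (joint weight–resolution map)."""

    wbar_grid: np.ndarray
    gamma_grid: np.ndarray
    values: np.ndarray
    diagnostic_name: str = "diagnostic"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.wbar_grid), len(self.gamma_grid)):
            raise ValueError("matrix shape must be (len(wbar), len(gamma))")


def _ensure_sorted_with(grid: np.ndarray, required: float) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if not np.any(np.isclose(grid, required)):
        grid = np.sort(np.append(grid, required))
    return grid


def mrf_soft(net: WeightedNetwork, r_grid=None, gamma: float = 1.0,
             n_runs: int = 20, seed: int | None = None) -> MRFCurve:
    """Optimized Q^w as a function of the soft-threshold power ``r``.

    r = 1 (the original normalized matrix — the conventional single-point
    statistic) is inserted into the grid if absent.  The curve's ``peak``
    property gives ``r_peak``, the grid argmax of the mean Q^w.
    """
    grid = _ensure_sorted_with(
        default_r_grid() if r_grid is None else r_grid, 1.0)
    if np.any(grid <= 0):
        raise ValueError("soft-threshold powers must be positive")
    net = normalize_weights(net)
    # common random numbers: one optimizer seed for every grid point, so the
    # curve varies only through the transform (constant for tied weights)
    run_seed = random.Random(seed).randrange(2**31)
    means, sds = [], []
    for r in grid:
        res = louvain_optimize(soft_threshold(net, float(r)), gamma=gamma,
                               n_runs=n_runs, seed=run_seed)
        means.append(res.mean("quality"))
        sds.append(res.sd("quality"))
    return MRFCurve("r", grid, np.array(means), np.array(sds),
                    np.full(grid.size, n_runs), diagnostic_name="Qw")


def _window_diagnostic(graph, diagnostic: str, gamma: float, n_runs: int,
                       seed, embedding: SpatialEmbedding | None,
                       laterality_n_random: int = 1000):
    """(mean, sd, n_samples) of one diagnostic on one windowed graph."""
    if diagnostic == "bipartivity":
        return bipartivity(graph), 0.0, 1
    rng = random.Random(seed)
    res = louvain_optimize(graph, gamma=gamma, n_runs=n_runs,
                           seed=rng.randrange(2**31))
    if diagnostic == "Q_binary":
        return res.mean("quality"), res.sd("quality"), n_runs
    if diagnostic in {"n_communities", "n_singletons", "n_nonsingleton"}:
        return res.mean(diagnostic), res.sd(diagnostic), n_runs
    if diagnostic == "laterality":
        vals = [
            community_laterality(p, embedding, n_random=laterality_n_random,
                                 seed=rng.randrange(2**31)).corrected
            for p in res.partitions
        ]
        vals = np.array(vals)
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        return float(vals.mean()), float(sd), n_runs
    raise ValueError(f"unknown diagnostic {diagnostic!r}; "
                     f"choose from {WINDOW_DIAGNOSTICS}")


def mrf_windowed(net: WeightedNetwork, s: float = 0.25, wbar_grid=None,
                 diagnostic: str = "Q_binary", gamma: float = 1.0,
                 n_runs: int = 20, seed: int | None = None,
                 weight_source: np.ndarray | None = None,
                 embedding: SpatialEmbedding | None = None,
                 n_points: int = 20) -> MRFCurve:
    """A binary-graph diagnostic as a function of the window weight W̄.

    Windows may rank edges by the network's own weights or by an alternate
    symmetric matrix over the same nodes (e.g. fiber length or Euclidean
    distance), keeping the edge support of the network.  Community-based
    diagnostics are averaged over optimizer restarts; bipartivity is
    deterministic.
    """
    if diagnostic == "laterality" and (
            embedding is None or not embedding.has_categories):
        raise ValueError("laterality requires an embedding with categories")
    if wbar_grid is None:
        windows = window_grid(s, n_points)
    else:
        windows = [ThresholdWindow(s, float(w)) for w in wbar_grid]
    master = random.Random(seed)
    grid, means, sds, counts = [], [], [], []
    for window in windows:
        graph = windowed_threshold(net, window, weight_source=weight_source)
        mean, sd, n = _window_diagnostic(
            graph, diagnostic, gamma, n_runs, master.randrange(2**31), embedding)
        grid.append(window.mean_percentile)
        means.append(mean)
        sds.append(sd)
        counts.append(n)
    return MRFCurve("wbar", np.array(grid), np.array(means), np.array(sds),
                    np.array(counts), diagnostic_name=diagnostic)


def mrf_resolution(net, gamma_grid=None, n_runs: int = 20,
                   seed: int | None = None,
                   embedding: SpatialEmbedding | None = None,
                   ) -> dict[str, MRFCurve]:
    """Community-structure curves versus the structural resolution γ.

    Returns curves of the non-singleton community count, the mean
    non-singleton community size, and — when an embedding is supplied — the
    normalized mean community radius ρ̄, all averaged over restarts.
    """
    grid = np.asarray(default_gamma_grid() if gamma_grid is None else gamma_grid,
                      dtype=float)
    master = random.Random(seed)
    rows = {"n_nonsingleton": [], "mean_nonsingleton_size": [], "radius": []}
    sds = {key: [] for key in rows}
    for gamma in grid:
        res = louvain_optimize(net, gamma=float(gamma), n_runs=n_runs,
                               seed=master.randrange(2**31))
        for key in ("n_nonsingleton", "mean_nonsingleton_size"):
            rows[key].append(res.mean(key))
            sds[key].append(res.sd(key))
        if embedding is not None:
            vals = np.array([
                community_radius(p, embedding).mean_normalized
                for p in res.partitions
            ])
            rows["radius"].append(float(vals.mean()))
            sds["radius"].append(float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
    out = {}
    for key in rows:
        if not rows[key]:
            continue
        out[key] = MRFCurve("gamma", grid, np.array(rows[key]),
                            np.array(sds[key]), np.full(grid.size, n_runs),
                            diagnostic_name=key)
    return out


def mrf_weight_resolution_map(net: WeightedNetwork, s: float = 0.25,
                              wbar_grid=None, gamma_grid=None,
                              n_runs: int = 20, seed: int | None = None,
                              n_points: int = 10,
                              ) -> tuple[MRFMatrix, MRFMatrix]:
    """Non-singleton (and total) community counts over the W̄ × γ plane."""
    if wbar_grid is None:
        windows = window_grid(s, n_points)
    else:
        windows = [ThresholdWindow(s, float(w)) for w in wbar_grid]
    gammas = np.asarray(
        default_gamma_grid(10) if gamma_grid is None else gamma_grid, float)
    master = random.Random(seed)
    non = np.empty((len(windows), len(gammas)))
    total = np.empty_like(non)
    for wi, window in enumerate(windows):
        graph = windowed_threshold(net, window)
        for gi, gamma in enumerate(gammas):
            res = louvain_optimize(graph, gamma=float(gamma), n_runs=n_runs,
                                   seed=master.randrange(2**31))
            non[wi, gi] = res.mean("n_nonsingleton")
            total[wi, gi] = res.mean("n_communities")
    wbars = np.array([w.mean_percentile for w in windows])
    return (MRFMatrix(wbars, gammas, non, "n_nonsingleton"),
            MRFMatrix(wbars, gammas, total, "n_communities"))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Permutation comparison of two groups of MRF curves."""

    grid: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    pointwise_p: np.ndarray
    curve_p: float
    n_permutations: int
    statistic: str = "mean_abs_difference"
    seed: int | None = None

    @property
    def mean_difference(self) -> np.ndarray:
        return self.mean_a - self.mean_b


def _curves_to_matrix(curves) -> tuple[np.ndarray, np.ndarray]:
    grid = curves[0].grid
    for c in curves[1:]:
        if not np.allclose(c.grid, grid):
            raise ValueError("curves must share a common grid")
    return grid, np.vstack([c.values for c in curves])


def permutation_group_test(group_a, group_b, n_perm: int = 999,
                           seed: int | None = None,
                           statistic: str = "mean_abs_difference",
                           ) -> GroupComparison:
    """Nonparametric permutation test between two groups of MRF curves.

    The pointwise statistic is the difference of group means at each grid
    point; the curve-level statistic summarizes the pointwise differences
    over the grid (``mean_abs_difference`` by default, ``max_abs_difference``
    as an alternative).  The null is built by permuting subject-to-group
    labels, and p-values use the add-one estimator
    ``(1 + #{null >= observed}) / (n_perm + 1)``, so they lie in (0, 1].
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two curves")
    if statistic not in {"mean_abs_difference", "max_abs_difference"}:
        raise ValueError(f"unknown curve statistic {statistic!r}")
    grid, mat_a = _curves_to_matrix(group_a)
    grid_b, mat_b = _curves_to_matrix(group_b)
    if not np.allclose(grid, grid_b):
        raise ValueError("groups must share a common grid")
    n_a = mat_a.shape[0]
    stacked = np.vstack([mat_a, mat_b])
    observed = mat_a.mean(axis=0) - mat_b.mean(axis=0)
    reduce_ = np.mean if statistic == "mean_abs_difference" else np.max
    observed_curve = float(reduce_(np.abs(observed)))

    rng = np.random.default_rng(seed)
    count_point = np.zeros(grid.size)
    count_curve = 0
    n_total = stacked.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        diff = stacked[perm[:n_a]].mean(axis=0) - stacked[perm[n_a:]].mean(axis=0)
        count_point += np.abs(diff) >= np.abs(observed) - 1e-15
        if reduce_(np.abs(diff)) >= observed_curve - 1e-15:
            count_curve += 1
    pointwise_p = (1.0 + count_point) / (n_perm + 1.0)
    curve_p = (1.0 + count_curve) / (n_perm + 1.0)
    return GroupComparison(
        grid=grid, mean_a=mat_a.mean(axis=0), mean_b=mat_b.mean(axis=0),
        pointwise_p=pointwise_p, curve_p=float(curve_p),
        n_permutations=n_perm, statistic=statistic, seed=seed,
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values for the pointwise grid (optional reporting aid)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out
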