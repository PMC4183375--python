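"""Mesoscopic response functions and the permutation group test."""

import numpy as np
import pytest

from mesoresolve import (MRFCurve, WeightedNetwork, generate_embedded_modular,
                         generate_er, generate_fractal_hierarchical,
                         generate_small_world, louvain_optimize,
                         mrf_resolution, mrf_soft, mrf_weight_resolution_map,
                         mrf_windowed, normalize_weights,
                         permutation_group_test, singleton_gamma)
from mesoresolve.mrf import benjamini_hochberg


def constant_curve(values, grid=None):
    values = np.asarray(values, dtype=float)
    grid = np.arange(len(values), dtype=float) if grid is None else grid
    return MRFCurve("gamma", grid, values, np.zeros_like(values),
                    np.ones(len(values), int))


class TestSoftMRF:
    def test_equal_weights_give_constant_curve(self):
        a = np.zeros((10, 10))
        for i in range(9):
            a[i, i + 1] = a[i + 1, i] = 0.5
        net = WeightedNetwork(a)
        curve = mrf_soft(net, r_grid=[0.1, 1.0, 10.0], n_runs=3, seed=0)
        assert np.ptp(curve.values) < 1e-12

    def test_r_equal_one_matches_direct_optimization(self):
        net, _ = generate_small_world(32, 150, 8, seed=1)
        curve = mrf_soft(net, r_grid=[0.5, 1.0, 2.0], n_runs=5, seed=2)
        direct = louvain_optimize(normalize_weights(net), 1.0, n_runs=5,
                                  seed=3).mean("quality")
        assert curve.at(1.0) == pytest.approx(direct, abs=0.03)

    def test_missing_r1_inserted(self):
        net, _ = generate_small_world(16, 40, 4, seed=4)
        curve = mrf_soft(net, r_grid=[0.5, 2.0], n_runs=2, seed=5)
        assert 1.0 in curve.grid.tolist()

    def test_continuous_weights_vanish_at_large_r(self):
        """ER with continuous weights: one edge dominates, Q^w -> 0."""
        net = generate_er(48, 400, seed=6)
        # r must be large relative to the edge count for one edge to dominate
        curve = mrf_soft(net, r_grid=[1.0, 1e4], n_runs=5, seed=7)
        assert curve.at(1e4) < 0.05
        assert curve.at(1.0) > curve.at(1e4)

    def test_discrete_ties_keep_modularity_at_large_r(self):
        """FH max-weight ties: large r converges to the top-level graph's Q."""
        net, truth = generate_fractal_hierarchical(64, 600, 8, seed=8)
        curve = mrf_soft(net, r_grid=[1.0, 100.0], n_runs=5, seed=9)
        top = WeightedNetwork((net.weights == 1.0).astype(float))
        q_top = louvain_optimize(top, 1.0, n_runs=5, seed=10).mean("quality")
        assert curve.at(100.0) == pytest.approx(q_top, abs=0.05)

    def test_peak_annotation(self):
        curve = constant_curve([0.1, 0.5, 0.3])
        assert curve.peak == (1.0, 0.5)


class TestWindowedMRF:
    def test_laterality_requires_categories(self):
        net = generate_er(16, 60, seed=0)
        with pytest.raises(ValueError, match="categor"):
            mrf_windowed(net, diagnostic="laterality", n_points=3)

    def test_unknown_diagnostic_rejected(self):
        net = generate_er(16, 60, seed=0)
        with pytest.raises(ValueError, match="unknown diagnostic"):
            mrf_windowed(net, diagnostic="clustering", n_points=3)

    def test_er_curve_flat(self):
        net = generate_er(64, 600, seed=1)
        curve = mrf_windowed(net, s=0.25, diagnostic="Q_binary", n_runs=3,
                             seed=2, n_points=8)
        assert np.ptp(curve.values) < 0.1

    def test_sw_two_regimes(self):
        net, _ = generate_small_world(64, 480, 8, seed=3)   # intra = 224 (47%)
        curve = mrf_windowed(net, s=0.25, diagnostic="Q_binary", n_runs=3,
                             seed=4, n_points=9)
        boundary = 1 - 224 / 480
        weak = curve.values[curve.grid <= boundary - 0.125]
        strong = curve.values[curve.grid >= boundary + 0.125]
        assert strong.min() > weak.max() + 0.2

    def test_bipartivity_deterministic_dispersion_zero(self):
        net = generate_er(32, 200, seed=5)
        curve = mrf_windowed(net, s=0.5, diagnostic="bipartivity", n_points=4)
        assert np.all(curve.dispersion == 0)
        assert np.all((curve.values >= 0.5) & (curve.values <= 1.0 + 1e-12))


class TestResolutionMRF:
    def test_endpoints_and_radius_trend(self):
        net, emb = generate_embedded_modular(64, 4, seed=0)
        hi = singleton_gamma(net) * 1.1
        grid = np.unique(np.concatenate([[1e-3], np.logspace(-1, 1, 7), [hi]]))
        curves = mrf_resolution(net, gamma_grid=grid, n_runs=5, seed=1,
                                embedding=emb)
        radius = curves["radius"]
        assert radius.values[0] == pytest.approx(1.0)   # single community
        assert radius.values[-1] == pytest.approx(0.0)  # all singletons
        rho = curves["radius"].values
        assert (stats_spearman(grid, rho)) < -0.7
        size = curves["mean_nonsingleton_size"].values
        assert size[0] == 64 and size[-1] == 0.0

    def test_no_radius_without_embedding(self):
        net = generate_er(16, 60, seed=2)
        curves = mrf_resolution(net, gamma_grid=[0.5, 1.0], n_runs=2, seed=3)
        assert "radius" not in curves
        assert set(curves) == {"n_nonsingleton", "mean_nonsingleton_size"}


def stats_spearman(x, y):
    from scipy.stats import spearmanr

    return spearmanr(x, y).statistic


class TestWeightResolutionMap:
    def test_shapes_and_fragmentation_limit(self):
        from mesoresolve import ThresholdWindow, windowed_threshold

        net = generate_er(48, 400, seed=0)
        hi = 1.1 * max(
            singleton_gamma(windowed_threshold(net, ThresholdWindow(0.25, w)))
            for w in (0.2, 0.5, 0.8))
        non, total = mrf_weight_resolution_map(
            net, s=0.25, wbar_grid=[0.2, 0.5, 0.8],
            gamma_grid=[0.5, 1.0, hi], n_runs=2, seed=1)
        assert non.values.shape == (3, 3)
        assert np.all(non.values[:, -1] == 0)        # full fragmentation
        assert np.all(total.values >= non.values)


class TestPermutationTest:
    def test_identical_groups_pointwise_p_one(self):
        curves = [constant_curve([0.1, 0.2, 0.3]) for _ in range(6)]
        res = permutation_group_test(curves[:3], curves[3:], n_perm=99, seed=0)
        assert np.all(res.pointwise_p == 1.0)
        assert res.curve_p == 1.0

    def test_separated_groups_small_p(self):
        rng = np.random.default_rng(1)
        group_a = [constant_curve(rng.normal(0.0, 0.01, 4)) for _ in range(8)]
        group_b = [constant_curve(rng.normal(1.0, 0.01, 4)) for _ in range(8)]
        res = permutation_group_test(group_a, group_b, n_perm=999, seed=2)
        assert res.curve_p == pytest.approx(1 / 1000)
        assert np.all(res.pointwise_p <= 0.01)
        assert np.all(np.abs(res.mean_difference) > 0.9)

    def test_pvalues_in_unit_interval_and_add_one(self):
        rng = np.random.default_rng(3)
        group_a = [constant_curve(rng.normal(size=3)) for _ in range(4)]
        group_b = [constant_curve(rng.normal(size=3)) for _ in range(4)]
        res = permutation_group_test(group_a, group_b, n_perm=49, seed=4)
        assert np.all((res.pointwise_p > 0) & (res.pointwise_p <= 1))
        # add-one estimator: granularity is 1/(n_perm + 1)
        assert np.all(np.round(res.pointwise_p * 50, 10) % 1 == 0)

    def test_pointwise_p_superuniform_under_null(self):
        """Exchangeable groups: P(p <= alpha) <= alpha (within MC noise)."""
        rng = np.random.default_rng(5)
        rejections = 0
        trials = 200
        for _ in range(trials):
            curves = [constant_curve(rng.normal(size=2)) for _ in range(10)]
            res = permutation_group_test(curves[:5], curves[5:], n_perm=39,
                                         seed=int(rng.integers(2**31)))
            rejections += res.pointwise_p[0] <= 0.1
        # binomial 4-sigma envelope around alpha = 0.1
        assert rejections / trials <= 0.1 + 4 * np.sqrt(0.1 * 0.9 / trials)

    def test_mismatched_grids_rejected(self):
        a = [constant_curve([0.1, 0.2]), constant_curve([0.1, 0.2])]
        b = [constant_curve([0.1, 0.2], grid=np.array([5.0, 6.0]))] * 2
        with pytest.raises(ValueError, match="grid"):
            permutation_group_test(a, b, n_perm=9)

    def test_max_statistic_variant(self):
        rng = np.random.default_rng(6)
        a = [constant_curve(rng.normal(size=3)) for _ in range(4)]
        b = [constant_curve(rng.normal(size=3)) for _ in range(4)]
        res = permutation_group_test(a, b, n_perm=99, seed=7,
                                     statistic="max_abs_difference")
        assert res.statistic == "max_abs_difference"
        assert 0 < res.curve_p <= 1


def test_benjamini_hochberg_adjustment():
    p = np.array([0.001, 0.01, 0.02, 0.8])
    q = benjamini_hochberg(p)
    assert np.all(q >= p)
    assert np.all(q <= 1)
    assert q[0] == pytest.approx(0.004)
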