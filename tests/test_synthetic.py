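"""Synthetic benchmark generators and ensemble construction."""

import numpy as np
import pytest
from scipy import stats

from mesoresolve import (EnsembleSpec, ModelSpec, ThresholdWindow,
                         cumulative_threshold, generate_embedded_modular,
                         generate_er, generate_fractal_hierarchical,
                         generate_ring_lattice, generate_small_world,
                         generate_two_group_ensembles, modularity_weighted,
                         Partition, sample_ensemble, windowed_threshold)
from mesoresolve.synthetic import fh_max_edges


def edge_weights(net):
    iu = np.triu_indices(net.n_nodes, k=1)
    w = net.weights[iu]
    return w[w > 0]


class TestER:
    def test_exact_edge_count_and_weight_range(self):
        net = generate_er(50, 300, seed=0)
        assert net.n_edges == 300
        w = edge_weights(net)
        assert np.all((w > 0) & (w <= 1))

    def test_saturated_budget_gives_complete_graph(self):
        net = generate_er(4, 6, seed=1)
        assert net.n_edges == 6

    def test_seeded_determinism(self):
        a = generate_er(100, 500, seed=1)
        b = generate_er(100, 500, seed=1)
        assert np.array_equal(a.weights, b.weights)

    def test_pair_selection_uniform(self):
        """Monte-Carlo frequency of each of the 15 pairs at N=6, M=3."""
        n_draws = 10_000
        counts = np.zeros((6, 6))
        rng_seed = iter(range(n_draws))
        for _ in range(n_draws):
            net = generate_er(6, 3, seed=next(rng_seed))
            counts += net.weights > 0
        iu = np.triu_indices(6, k=1)
        freq = counts[iu]
        p = 3 / 15
        bound = 4 * np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(freq - n_draws * p) < bound)

    def test_infeasible_budget_rejected(self):
        with pytest.raises(ValueError, match="n_edges"):
            generate_er(4, 7, seed=0)


class TestRingLattice:
    def test_pure_hexagon(self):
        net = generate_ring_lattice(6, 6)
        assert net.n_edges == 6
        assert np.all(edge_weights(net) == 1.0)

    def test_hexagon_plus_three_chords(self):
        net = generate_ring_lattice(6, 9)
        w = net.weights
        # full ring at weight 1
        for i in range(6):
            assert w[i, (i + 1) % 6] == 1.0
        # distance-2 chords at the 3 smallest starting indices, weight 0.5
        assert w[0, 2] == w[1, 3] == w[2, 4] == 0.5
        assert w[3, 5] == 0.0
        assert net.n_edges == 9

    def test_weights_nonincreasing_with_shell_distance(self):
        net = generate_ring_lattice(20, 70)
        n = net.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if net.weights[i, j] > 0:
                    d = min(j - i, n - (j - i))
                    assert net.weights[i, j] == pytest.approx(1 - (d - 1) / 4)

    def test_incomplete_ring_logged(self, caplog):
        net = generate_ring_lattice(10, 7)
        assert net.n_edges == 7
        assert "incomplete" in caplog.text


class TestSmallWorld:
    def test_clique_edges_all_present(self):
        net, labels = generate_small_world(8, 14, 4, seed=0)
        for i in range(8):
            for j in range(i + 1, 8):
                if labels[i] == labels[j]:
                    assert net.weights[i, j] > 0
        assert net.n_edges == 14

    def test_disjoint_weight_bands(self):
        net, labels = generate_small_world(32, 200, 8, seed=1)
        same = labels[:, None] == labels[None, :]
        intra = net.weights[(net.weights > 0) & same]
        inter = net.weights[(net.weights > 0) & ~same]
        assert intra.min() > inter.max()
        assert intra.min() >= 0.6 and inter.max() <= 0.4

    def test_top_band_window_recovers_cliques(self):
        net, labels = generate_small_world(32, 240, 8, seed=2)
        n_intra = 4 * 28
        graph = windowed_threshold(net, ThresholdWindow(n_intra / 240,
                                                        1 - n_intra / 480))
        expected = ((labels[:, None] == labels[None, :])
                    & ~np.eye(32, dtype=bool)).astype(float)
        assert np.array_equal(graph.adjacency, expected)

    def test_non_dyadic_node_count(self):
        net, labels = generate_small_world(50, 500, 8, seed=3)
        assert net.n_nodes == 50
        assert net.n_edges == 500

    def test_budget_below_intra_subsamples(self, caplog):
        net, _ = generate_small_world(16, 30, 8, seed=4)   # intra would be 56
        assert net.n_edges == 30
        assert "subsampling" in caplog.text


class TestFractalHierarchical:
    def test_weight_ladder_and_level_count(self):
        net, truth = generate_fractal_hierarchical(64, 600, 8, seed=0)
        w = np.unique(edge_weights(net))
        assert truth["n_levels"] == 4
        assert np.allclose(np.sort(w), [0.125, 0.25, 0.5, 1.0])
        # level-1 weight strictly dominates every other level
        assert w.max() == 1.0

    def test_elementary_groups_complete(self):
        net, truth = generate_fractal_hierarchical(64, 600, 8, seed=1)
        groups = truth["levels"][1]
        same = groups[:, None] == groups[None, :]
        off_diag = same & ~np.eye(64, dtype=bool)
        assert np.all(net.weights[off_diag] == 1.0)

    def test_expected_edge_count(self):
        target = 600
        counts = [generate_fractal_hierarchical(64, target, 8, seed=s)[0].n_edges
                  for s in range(200)]
        sd = np.std(counts, ddof=1)
        assert abs(np.mean(counts) - target) < 4 * sd / np.sqrt(200) + 1e-9

    def test_infeasible_density_reports_maximum(self):
        with pytest.raises(ValueError, match="maximal feasible"):
            generate_fractal_hierarchical(64, 1900, 8, seed=0)
        assert fh_max_edges(64, 8) < 1900

    def test_surplus_deletion_keeps_requested_size(self):
        net, truth = generate_fractal_hierarchical(50, 400, 8, seed=2)
        assert net.n_nodes == 50
        assert len(truth["levels"][1]) == 50


class TestEnsembles:
    def _spec(self, sd, size, seed=0):
        return EnsembleSpec(ModelSpec("er", 40, 300), edge_count_mean=300,
                            edge_count_sd=sd, size=size, seed=seed)

    def test_zero_sd_fixes_edge_count(self):
        nets = sample_ensemble(self._spec(0.0, 5))
        assert {n.n_edges for n in nets} == {300}

    def test_gaussian_mean_clt_bound(self):
        nets = sample_ensemble(self._spec(20.0, 50))
        counts = [n.n_edges for n in nets]
        assert abs(np.mean(counts) - 300) < 4 * 20 / np.sqrt(50)

    def test_master_seed_reproducibility(self):
        a = sample_ensemble(self._spec(10.0, 4, seed=7))
        b = sample_ensemble(self._spec(10.0, 4, seed=7))
        assert all(np.array_equal(x.weights, y.weights) for x, y in zip(a, b))


class TestFixtures:
    def test_embedded_modular_structure(self):
        net, emb = generate_embedded_modular(64, 4, seed=0)
        assert emb.has_categories
        assert np.bincount(emb.categories).tolist() == [32, 32]
        # module clouds are tight relative to centroid spacing
        labels = np.repeat(np.arange(4), 16)
        for mod in range(4):
            cloud = emb.coordinates[labels == mod]
            assert cloud.std(axis=0).max() < 3.0

    def test_two_group_effect_raises_modularity(self):
        from mesoresolve import louvain_optimize

        group_a, group_b = generate_two_group_ensembles(8, effect=1.0, seed=1)
        qa = np.mean([louvain_optimize(n, 1.0, n_runs=3, seed=i).mean("quality")
                      for i, n in enumerate(group_a)])
        qb = np.mean([louvain_optimize(n, 1.0, n_runs=3, seed=i).mean("quality")
                      for i, n in enumerate(group_b)])
        assert qb > qa

    def test_two_group_determinism(self):
        a1, b1 = generate_two_group_ensembles(3, effect=0.0, seed=5)
        a2, b2 = generate_two_group_ensembles(3, effect=0.0, seed=5)
        assert np.array_equal(a1[0].weights, a2[0].weights)
        assert np.array_equal(b1[-1].weights, b2[-1].weights)


def test_model_spec_validation():
    with pytest.raises(ValueError, match="unknown model"):
        ModelSpec("ws", 10, 20)
    with pytest.raises(ValueError, match="cluster"):
        ModelSpec("sw", 10, 20, cluster_size=1)
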