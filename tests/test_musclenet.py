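import numpy as np
import pytest

from walknet import musclenet, synergy
from walknet.imc import CoherenceComponents, CoherenceSet
from walknet.muscles import N_MUSCLES, pair_index


def toy_multiplex(rng, n=6, n_layers=2, density=0.7):
    layers = []
    for _ in range(n_layers):
        M = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), 1)
        layers.append(M + M.T)
    return musclenet.MultiplexNetwork(
        layers=layers, layer_labels=[f"L{i}" for i in range(n_layers)],
        node_labels=[str(i) for i in range(n)],
    )


def brute_force_threshold(layers):
    """Exhaustive search over candidate thresholds (edge-weight values)."""
    n = layers[0].shape[0]
    candidates = sorted(
        {w for L in layers for w in L[np.triu_indices(n, 1)] if w > 0}
    )
    best = None
    for tau in candidates:
        ok = all(
            any(L[i, j] >= tau for L in layers for j in range(n) if j != i)
            for i in range(n)
        )
        if ok:
            best = tau
    return best


class TestMultiplexNetwork:
    def test_asymmetric_layer_rejected(self):
        M = np.zeros((4, 4))
        M[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            musclenet.MultiplexNetwork([M], ["a"], list("wxyz"))

    def test_negative_weights_rejected(self):
        M = -np.ones((3, 3))
        np.fill_diagonal(M, 0)
        with pytest.raises(ValueError, match="negative"):
            musclenet.MultiplexNetwork([M], ["a"], list("xyz"))

    def test_diagonal_zeroed(self):
        M = np.ones((3, 3))
        net = musclenet.MultiplexNetwork([M], ["a"], list("xyz"))
        assert np.all(np.diag(net.layers[0]) == 0)


class TestSynergyLayers:
    def _model(self, W, A, n=100):
        m = W.shape[1]
        return synergy.SynergyModel(
            W=W, A=A, m=m, lambda_total=90.0,
            lambda_per_synergy=np.zeros(m),
        )

    def test_one_hot_weight_gives_empty_layer(self):
        W = np.zeros((N_MUSCLES, 1))
        W[0, 0] = 1.0
        A = np.ones((1, 100))
        net = musclenet.synergy_layers(self._model(W, A), n=100)
        assert np.all(net.layers[0] == 0)

    def test_single_edge_weighted_by_waveform_integral(self):
        W = np.zeros((N_MUSCLES, 1))
        W[0, 0] = 1.0
        W[1, 0] = 1.0
        A = np.full((1, 100), 0.02)  # integral over one 0-100% stride = 2
        net = musclenet.synergy_layers(self._model(W, A), n=100)
        assert net.layers[0][0, 1] == pytest.approx(2.0)
        assert net.layers[0].sum() == pytest.approx(4.0)  # symmetric edge

    def test_zero_waveform_gives_zero_layer(self):
        W = np.abs(np.random.default_rng(0).random((N_MUSCLES, 1)))
        A = np.zeros((1, 100))
        net = musclenet.synergy_layers(self._model(W, A), n=100)
        assert np.all(net.layers[0] == 0)


class TestCoherenceLayers:
    def _fake_set_and_components(self, subjects, conditions, weight_fn):
        pairs = pair_index(N_MUSCLES)
        columns = [
            (s, c, p) for s in subjects for c in conditions for p in pairs
        ]
        A = np.array([[weight_fn(s, c, p) for (s, c, p) in columns]])
        cset = CoherenceSet(
            freqs=np.arange(4.0, 61.0),
            C2=np.zeros((57, len(columns))),
            pairs=pairs,
            columns=columns,
        )
        comps = CoherenceComponents(
            W=np.ones((57, 1)), A=A, m=1, lambda_profile={1: 60.0}, lambda_total=60.0
        )
        return comps, cset

    def test_single_subject_averaging_identity(self):
        comps, cset = self._fake_set_and_components(
            [1], ["1:1"], lambda s, c, p: float(p[0] + p[1])
        )
        net = musclenet.coherence_layers(comps, cset)
        assert len(net.layers) == 1
        assert net.layers[0][2, 5] == pytest.approx(7.0)

    def test_layer_cardinality(self):
        comps, cset = self._fake_set_and_components(
            [1], ["2:1", "T", "1:1"], lambda s, c, p: 1.0
        )
        comps3 = CoherenceComponents(
            W=np.ones((57, 3)), A=np.tile(comps.A, (3, 1)), m=3,
            lambda_profile={3: 60.0}, lambda_total=60.0,
        )
        net = musclenet.coherence_layers(comps3, cset)
        assert len(net.layers) == 9

    def test_two_block_structure_preserved(self):
        block = lambda i: 0 if i < 13 else 1

        def w(s, c, p):
            return 1.0 if block(p[0]) == block(p[1]) else 0.05

        comps, cset = self._fake_set_and_components([1, 2], ["1:1"], w)
        net = musclenet.coherence_layers(comps, cset)
        L = net.layers[0]
        within = [L[i, j] for i, j in pair_index() if block(i) == block(j)]
        between = [L[i, j] for i, j in pair_index() if block(i) != block(j)]
        assert np.mean(within) / np.mean(between) > 2

    def test_no_condition_rejected(self):
        comps, cset = self._fake_set_and_components([1], ["1:1"], lambda s, c, p: 1.0)
        cset.columns = [(s, "??", p) for s, _, p in cset.columns]
        with pytest.raises(ValueError, match="condition"):
            musclenet.coherence_layers(comps, cset)


class TestMinimallyConnect:
    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net = toy_multiplex(rng)
            if all(L.sum() == 0 for L in net.layers):
                continue
            _, tau, _ = musclenet.minimally_connect(net)
            assert tau == pytest.approx(brute_force_threshold(net.layers), abs=1e-12)

    def test_weak_node_edge_preserved(self):
        L = np.zeros((4, 4))
        L[0, 1] = L[1, 0] = 1.0
        L[1, 2] = L[2, 1] = 0.9
        L[2, 3] = L[3, 2] = 0.01  # node 3 hangs on this weak edge
        net = musclenet.MultiplexNetwork([L], ["a"], list("wxyz"))
        thr, tau, _ = musclenet.minimally_connect(net)
        assert tau <= 0.01
        assert thr.layers[0][2, 3] == pytest.approx(0.01)

    def test_equal_weights_keep_everything(self):
        L = np.ones((5, 5))
        net = musclenet.MultiplexNetwork([L], ["a"], list("abcde"))
        thr, tau, stats = musclenet.minimally_connect(net)
        assert tau == pytest.approx(1.0)
        assert stats["n_removed"] == 0
        np.testing.assert_array_equal(thr.layers[0], net.layers[0])

    def test_equal_edge_count_across_layers(self):
        rng = np.random.default_rng(3)
        net = toy_multiplex(rng, n=8, n_layers=3)
        thr, tau, stats = musclenet.minimally_connect(net)
        counts = [int((L > 0).sum() // 2) for L in thr.layers]
        k = stats["edges_per_layer"]
        assert all(c <= k for c in counts)
        assert max(counts) == k

    def test_never_disconnects_connected_node(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            net = toy_multiplex(rng, n=7, n_layers=2, density=0.5)
            had_edge = np.stack(net.layers).sum(axis=0).sum(axis=1) > 0
            if not had_edge.any():
                continue
            thr, _, _ = musclenet.minimally_connect(net)
            has_edge = np.stack(thr.layers).sum(axis=0).sum(axis=1) > 0
            assert np.all(has_edge[had_edge])

    def test_symmetry_and_zero_diagonal_preserved(self):
        rng = np.random.default_rng(5)
        net = toy_multiplex(rng)
        thr, _, _ = musclenet.minimally_connect(net)
        for L in thr.layers:
            np.testing.assert_allclose(L, L.T)
            assert np.all(np.diag(L) == 0)


class TestCommunities:
    def test_two_cliques_recovered(self):
        n = 26
        L = np.zeros((n, n))
        for grp in (range(13), range(13, 26)):
            for i in grp:
                for j in grp:
                    if i != j:
                        L[i, j] = 1.0
        net = musclenet.MultiplexNetwork(
            [L, L.copy()], ["a", "b"], [str(i) for i in range(n)]
        )
        part = musclenet.communities(net, seed=0)
        truth = np.array([0] * 13 + [1] * 13)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, part.membership) == 1.0

    def test_single_clique_one_community(self):
        L = np.ones((8, 8))
        net = musclenet.MultiplexNetwork([L], ["a"], [str(i) for i in range(8)])
        part = musclenet.communities(net, seed=0)
        assert part.n_communities == 1

    def test_planted_four_modules_weighted(self):
        rng = np.random.default_rng(0)
        n = 24
        truth = np.repeat(np.arange(4), 6)
        from sklearn.metrics import adjusted_rand_score

        for seed in range(10):
            L = np.full((n, n), 0.05)
            for c in range(4):
                idx = np.flatnonzero(truth == c)
                L[np.ix_(idx, idx)] = 1.0
            np.fill_diagonal(L, 0)
            net = musclenet.MultiplexNetwork([L], ["a"], [str(i) for i in range(n)])
            part = musclenet.communities(net, seed=seed)
            assert adjusted_rand_score(truth, part.membership) == 1.0

    def test_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(1)
        net = toy_multiplex(rng, n=10, n_layers=2)
        scaled = musclenet.MultiplexNetwork(
            [7.0 * L for L in net.layers], net.layer_labels, net.node_labels
        )
        a = musclenet.communities(net, seed=3)
        b = musclenet.communities(scaled, seed=3)
        np.testing.assert_array_equal(a.membership, b.membership)

    def test_empty_network_rejected(self):
        net = musclenet.MultiplexNetwork(
            [np.zeros((4, 4))], ["a"], list("wxyz")
        )
        with pytest.raises(ValueError, match="edges"):
            musclenet.communities(net)

    def test_per_layer_modularity_reported(self):
        rng = np.random.default_rng(2)
        net = toy_multiplex(rng, n=8, n_layers=3)
        part = musclenet.communities(net, seed=0)
        assert len(part.modularity_per_layer) == 3


class TestLayerMetrics:
    def test_complete_graph_closed_form(self):
        n = 7
        L = np.ones((n, n))
        np.fill_diagonal(L, 0)
        m = musclenet.layer_metrics(L)
        assert m.global_efficiency == pytest.approx(1.0)
        assert m.transitivity == pytest.approx(1.0)
        assert m.average_strength == pytest.approx(n - 1)

    def test_star_graph_no_triangles(self):
        L = np.zeros((6, 6))
        L[0, 1:] = 1.0
        L[1:, 0] = 1.0
        assert musclenet.layer_metrics(L).transitivity == 0.0

    def test_path_efficiency_hand_computed(self):
        L = np.zeros((5, 5))
        for i in range(4):
            L[i, i + 1] = L[i + 1, i] = 1.0
        expected = (4 * 1 + 3 * 0.5 + 2 / 3 + 1 * 0.25) / 10
        assert musclenet.layer_metrics(L).global_efficiency == pytest.approx(expected)

    def test_all_zero_layer_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            m = musclenet.layer_metrics(np.zeros((4, 4)))
        assert (m.global_efficiency, m.transitivity, m.average_strength) == (0, 0, 0)

    def test_metrics_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            M = np.triu(rng.random((8, 8)), 1)
            M = M + M.T
            m = musclenet.layer_metrics(M)
            assert 0 <= m.global_efficiency <= 1 + 1e-9
            assert 0 <= m.transitivity <= 1 + 1e-9
            assert m.average_strength >= 0


class TestComparePartitions:
    def brute_force_rand(self, p1, p2):
        from itertools import combinations

        agree = 0
        pairs = list(combinations(range(len(p1)), 2))
        for i, j in pairs:
            agree += (p1[i] == p1[j]) == (p2[i] == p2[j])
        return agree / len(pairs)

    def test_identical_partitions(self):
        p = np.array([0, 0, 1, 1, 2])
        res = musclenet.compare_partitions(p, p, n_perm=50, seed=0)
        assert res["rand"] == 1.0
        assert res["adjusted_rand"] == 1.0

    def test_one_community_vs_singletons_matches_brute_force(self):
        p1 = np.zeros(4, dtype=int)
        p2 = np.arange(4)
        res = musclenet.compare_partitions(p1, p2, n_perm=50, seed=0)
        oracle = self.brute_force_rand(p1, p2)
        assert res["rand"] == pytest.approx(oracle)
        assert oracle == 0.0  # no pair agrees in either direction

    def test_random_partitions_ari_near_zero(self):
        rng = np.random.default_rng(0)
        aris = []
        for _ in range(30):
            p1 = rng.integers(0, 3, 30)
            p2 = rng.integers(0, 3, 30)
            aris.append(
                musclenet.compare_partitions(p1, p2, n_perm=10, seed=0)["adjusted_rand"]
            )
        assert abs(np.mean(aris)) < 0.05

    def test_permutation_p_value_significant_for_matched(self):
        p = np.repeat([0, 1, 2], 8)
        res = musclenet.compare_partitions(p, p, n_perm=500, seed=0)
        assert res["p_value"] < 0.01

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            musclenet.compare_partitions(np.zeros(3), np.zeros(4))

    def test_singleton_node_set_rejected(self):
        with pytest.raises(ValueError):
            musclenet.compare_partitions(np.zeros(1), np.zeros(1))
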