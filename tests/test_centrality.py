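import numpy as np
import pytest

from ggmclust import (
    DegenerateValuesError,
    MissingCommunityError,
    WeightedNetwork,
    betweenness,
    bridge_expected_influence,
    bridge_strength,
    centrality_long,
    centrality_table,
    closeness,
    expected_influence,
    shortest_path_lengths,
    strength,
    z_standardize,
)

from _oracles import brute_force_betweenness, brute_force_closeness, brute_force_geodesics


def _net(weights, names=None):
    weights = np.asarray(weights, float)
    names = names or [chr(97 + i) for i in range(weights.shape[0])]
    return WeightedNetwork(weights, names)


def _random_net(rng, p=6, density=0.5):
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(-1, 1)
    return _net(W)


CHAIN = _net([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])
MIXED = _net([[0, 0.5, 0], [0.5, 0, -0.3], [0, -0.3, 0]])


class TestOneStepIndexes:
    def test_empty_network_all_zero(self):
        net = _net(np.zeros((4, 4)))
        assert not strength(net).any()
        assert not expected_influence(net).any()

    def test_signed_sums_by_hand(self):
        assert strength(MIXED)[1] == pytest.approx(0.8)
        assert expected_influence(MIXED)[1] == pytest.approx(0.2)

    def test_matches_naive_double_loop(self, rng):
        net = _random_net(rng)
        p = net.p
        s = np.zeros(p)
        ei = np.zeros(p)
        for i in range(p):
            for j in range(p):
                s[i] += abs(net.weights[i, j])
                ei[i] += net.weights[i, j]
        np.testing.assert_allclose(strength(net), s)
        np.testing.assert_allclose(expected_influence(net), ei)

    def test_strength_dominates_expected_influence(self, rng):
        for _ in range(5):
            net = _random_net(rng)
            assert np.all(strength(net) >= np.abs(expected_influence(net)) - 1e-12)


class TestGeodesics:
    def test_chain_distances_by_hand(self):
        D = shortest_path_lengths(CHAIN)
        assert D[0, 1] == pytest.approx(2.0)
        assert D[1, 2] == pytest.approx(2.0)
        assert D[0, 2] == pytest.approx(4.0)

    def test_complete_unit_weights(self):
        W = np.ones((4, 4)) - np.eye(4)
        D = shortest_path_lengths(_net(W))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(D[off], 1.0)

    def test_isolated_node_unreachable(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        D = shortest_path_lengths(_net(W))
        assert np.isinf(D[0, 2]) and np.isinf(D[2, 1])

    def test_matches_brute_force_enumeration(self, rng):
        net = _random_net(rng, p=6)
        D_brute, _ = brute_force_geodesics(net.weights)
        np.testing.assert_allclose(shortest_path_lengths(net), D_brute)


class TestCloseness:
    def test_chain_middle_value(self):
        assert closeness(CHAIN)[1] == pytest.approx(0.25)

    def test_complete_unit_network_symmetric(self):
        W = np.ones((4, 4)) - np.eye(4)
        np.testing.assert_allclose(closeness(_net(W)), 1.0 / 3.0)

    def test_isolated_node_gets_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        assert closeness(_net(W)).tolist() == [0.0, 0.0, 0.0]  # all see an inf

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            net = _random_net(rng, p=int(rng.integers(4, 8)))
            np.testing.assert_allclose(
                closeness(net), brute_force_closeness(net.weights), atol=1e-10
            )


class TestBetweenness:
    def test_chain_middle_node(self):
        b = betweenness(CHAIN)
        assert b.tolist() == [0.0, 1.0, 0.0]

    def test_complete_unit_network_all_zero(self):
        W = np.ones((5, 5)) - np.eye(5)
        assert not betweenness(_net(W)).any()

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            net = _random_net(rng, p=int(rng.integers(4, 8)))
            np.testing.assert_allclose(
                betweenness(net), brute_force_betweenness(net.weights), atol=1e-8
            )


class TestBridgeIndexes:
    COMM = {"a": "C1", "b": "C1", "c": "C2"}

    def test_single_community_all_zero(self):
        comm = {"a": "C", "b": "C", "c": "C"}
        assert not bridge_strength(MIXED, comm).any()
        assert not bridge_expected_influence(MIXED, comm).any()

    def test_hand_computed_cross_community_sums(self):
        net = _net([[0, 0.9, 0], [0.9, 0, -0.4], [0, -0.4, 0]])
        bs = bridge_strength(net, self.COMM)
        bei = bridge_expected_influence(net, self.COMM)
        assert bs[1] == pytest.approx(0.4)
        assert bs[0] == pytest.approx(0.0)
        assert bei[1] == pytest.approx(-0.4)

    def test_matches_naive_masked_sums(self, rng):
        net = _random_net(rng, p=7)
        comms = {n: f"G{i % 3}" for i, n in enumerate(net.variable_names)}
        p = net.p
        bs = np.zeros(p)
        bei = np.zeros(p)
        for i, ni in enumerate(net.variable_names):
            for j, nj in enumerate(net.variable_names):
                if comms[ni] != comms[nj]:
                    bs[i] += abs(net.weights[i, j])
                    bei[i] += net.weights[i, j]
        np.testing.assert_allclose(bridge_strength(net, comms), bs)
        np.testing.assert_allclose(bridge_expected_influence(net, comms), bei)
        assert np.all(bs >= np.abs(bei) - 1e-12)

    def test_unmapped_node_rejected(self):
        with pytest.raises(MissingCommunityError):
            bridge_strength(MIXED, {"a": "C1", "b": "C1"})


class TestScaleCovariance:
    def test_rescaling_weights(self, rng):
        net = _random_net(rng)
        scaled = WeightedNetwork(3.0 * net.weights, net.variable_names)
        np.testing.assert_allclose(strength(scaled), 3.0 * strength(net))
        np.testing.assert_allclose(
            expected_influence(scaled), 3.0 * expected_influence(net)
        )
        np.testing.assert_allclose(
            shortest_path_lengths(scaled), shortest_path_lengths(net) / 3.0
        )
        np.testing.assert_allclose(betweenness(scaled), betweenness(net), atol=1e-10)


class TestZStandardize:
    def test_closed_form_triplet(self):
        np.testing.assert_allclose(
            z_standardize([1.0, 2.0, 3.0]), [-1.2247, 0.0, 1.2247], atol=1e-4
        )

    def test_idempotent_on_standardized_input(self, rng):
        z = z_standardize(rng.normal(size=20))
        np.testing.assert_allclose(z_standardize(z), z, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateValuesError):
            z_standardize([2.0, 2.0, 2.0])


class TestCentralityTable:
    def test_z_columns_standardized(self, rng):
        net = _random_net(rng, p=8, density=0.7)
        comms = {n: ("A" if i < 4 else "B") for i, n in enumerate(net.variable_names)}
        table = centrality_table(net, comms)
        for col in table.columns:
            if col.endswith("_z"):
                vals = table[col].to_numpy()
                assert vals.mean() == pytest.approx(0.0, abs=1e-10)
                assert vals.std() == pytest.approx(1.0, abs=1e-10)
        assert "bridge_strength" in table.columns
        assert list(table["community"]) == [comms[n] for n in net.variable_names]

    def test_long_format_covers_all_cells(self, rng):
        net = _random_net(rng, p=5)
        table = centrality_table(net)
        long = centrality_long(table)
        n_value_cols = len([c for c in table.columns if c != "community"])
        assert len(long) == 5 * n_value_cols
        assert set(long.columns) == {"node", "index", "value"}
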