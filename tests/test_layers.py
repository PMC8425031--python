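import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tgso.io_formats import ExpressionTable, LocalizationTable
from tgso.layers import (
    build_adn,
    build_cen,
    build_cln,
    colocalization_weight,
    connection_weight,
    dbn_weight,
    location_frequency,
    pearson_cc,
    self_localization_score,
)

import oracles
from conftest import make_network, random_instance


def layer_as_dict(layer, network):
    return {
        (i, j): layer.matrix[i, j] for i, j in network.edges()
    }


class TestDBN:
    def test_path_endpoint_edge(self, path3):
        net, _ = path3
        assert dbn_weight(net, 0, 1) == 1.0

    def test_four_cycle_edge(self):
        net, _ = make_network(4, [(0, 1), (1, 2), (2, 3), (0, 3)])
        assert dbn_weight(net, 0, 1) == 0.5

    def test_non_edge_rejected(self, path3):
        net, _ = path3
        with pytest.raises(ValueError):
            dbn_weight(net, 0, 2)
        with pytest.raises(ValueError):
            dbn_weight(net, 1, 1)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_graphs_match_neighbor_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        edges = [(i, j) for i, j in zip(*np.triu_indices(12, k=1))
                 if rng.random() < 0.3]
        if not edges:
            pytest.skip("empty draw")
        net, _ = make_network(12, edges)
        adj = oracles.adjacency_dict(12, edges)
        for i, j in edges:
            assert dbn_weight(net, i, j) == pytest.approx(
                oracles.dbn(adj, i, j), abs=1e-12
            )


class TestADN:
    def test_triangle_all_ones(self, triangle):
        net, _ = triangle
        adn = build_adn(net)
        assert all(adn.matrix[i, j] == 1.0 for i, j in net.edges())

    def test_star_all_ones(self, star4):
        net, _ = star4
        adn = build_adn(net)
        assert all(adn.matrix[i, j] == 1.0 for i, j in net.edges())

    def test_random_graph_elementwise(self):
        net, expr, loc, orth = random_instance(11, n=15)
        adn = build_adn(net)
        adj = oracles.adjacency_dict(net.n_nodes, list(net.edges()))
        for i, j in net.edges():
            assert adn.matrix[i, j] == pytest.approx(
                oracles.dbn(adj, i, j), abs=1e-12
            )


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_cc(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_cc(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == pytest.approx(-1.0)

    def test_constant_vector_convention(self):
        assert pearson_cc(np.array([2.0, 2, 2]), np.array([1.0, 2, 3])) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson_cc(np.array([1.0, 2]), np.array([1.0, 2, 3]))
        with pytest.raises(ValueError):
            pearson_cc(np.array([1.0]), np.array([2.0]))

    def test_random_pairs_match_textbook_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(size=36)
            y = rng.normal(size=36)
            assert pearson_cc(x, y) == pytest.approx(
                oracles.pcc(x.tolist(), y.tolist()), abs=1e-12
            )
            assert -1.0 - 1e-12 <= pearson_cc(x, y) <= 1.0 + 1e-12


class TestConnection:
    def test_no_common_neighbors_is_plain_pcc(self):
        net, ids = make_network(2, [(0, 1)])
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(2, 6)), index=ids)
        expr = ExpressionTable(data=data)
        expected = oracles.pcc(data.iloc[0].tolist(), data.iloc[1].tolist())
        assert connection_weight(net, expr, 0, 1) == pytest.approx(
            max(expected, 0.0), abs=1e-12
        )

    def test_identical_profiles_with_common_neighbor(self):
        net, ids = make_network(3, [(0, 1), (0, 2), (1, 2)])
        expr = ExpressionTable(
            data=pd.DataFrame([[1.0, 2, 3]] * 3, index=ids)
        )
        assert connection_weight(net, expr, 0, 1) == pytest.approx(2.0)

    def test_uncovered_network_gives_zero_layer(self, triangle):
        net, _ = triangle
        expr = ExpressionTable(data=pd.DataFrame(
            [[1.0, 2.0]], index=["unrelated"]
        ))
        cen = build_cen(net, expr)
        assert cen.matrix.nnz == 0 or cen.matrix.max() == 0.0

    def test_random_instance_matches_loop_oracle(self):
        net, expr, loc, orth = random_instance(5, n=10, t=36, coverage=0.8)
        cen = build_cen(net, expr)
        adj = oracles.adjacency_dict(net.n_nodes, list(net.edges()))
        profiles = {
            i: expr.vector(pid).tolist() if expr.has(pid) else None
            for i, pid in enumerate(net.node_ids)
        }
        for i, j in net.edges():
            assert cen.matrix[i, j] == pytest.approx(
                oracles.connection(adj, profiles, i, j), abs=1e-12
            )


class TestLocationFrequency:
    def test_single_compartment(self):
        loc = LocalizationTable(
            sets={"P1": frozenset({"Nucleus"}), "P2": frozenset({"Nucleus"})},
            vocabulary=["Nucleus"],
        )
        assert location_frequency(loc).scores == {"Nucleus": 1.0}

    def test_counts_normalized(self):
        loc = LocalizationTable(
            sets={
                "P1": frozenset({"Nucleus"}),
                "P2": frozenset({"Nucleus"}),
                "P3": frozenset({"Nucleus", "Cytosol"}),
            },
            vocabulary=["Nucleus", "Cytosol"],
        )
        freq = location_frequency(loc)
        assert freq.scores["Nucleus"] == pytest.approx(0.75)
        assert freq.scores["Cytosol"] == pytest.approx(0.25)

    def test_random_annotation_matches_counting_oracle(self):
        rng = np.random.default_rng(9)
        vocab = [f"C{i:02d}" for i in range(11)]
        sets = {
            f"P{i}": frozenset(
                rng.choice(vocab, size=rng.integers(1, 4), replace=False).tolist()
            )
            for i in range(200)
        }
        loc = LocalizationTable(sets=sets, vocabulary=vocab)
        freq = location_frequency(loc)
        expected = oracles.sub_scores(sets)
        for c in vocab:
            assert freq.scores[c] == pytest.approx(expected.get(c, 0.0), abs=1e-12)
        assert sum(freq.scores.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_annotations_is_an_error(self):
        loc = LocalizationTable(sets={}, vocabulary=["Nucleus"])
        with pytest.raises(ValueError, match="localization data"):
            location_frequency(loc)


class TestColocalization:
    @pytest.fixture
    def freq_loc(self):
        loc = LocalizationTable(
            sets={
                "P1": frozenset({"A"}),
                "P2": frozenset({"A"}),
                "P3": frozenset({"B"}),
                "P4": frozenset({"B", "C"}),
                "P5": frozenset({"C"}),
            },
            vocabulary=["A", "B", "C"],
        )
        return location_frequency(loc), loc

    def test_unannotated_s_score_zero(self, freq_loc):
        freq, loc = freq_loc
        assert self_localization_score(freq, loc, "absent") == 0.0

    def test_full_vocabulary_s_score_one(self):
        loc = LocalizationTable(
            sets={"P1": frozenset({"A", "B"})}, vocabulary=["A", "B"]
        )
        freq = location_frequency(loc)
        assert self_localization_score(freq, loc, "P1") == pytest.approx(1.0)

    def test_disjoint_sets_zero(self, freq_loc):
        freq, loc = freq_loc
        assert colocalization_weight(freq, loc, "P1", "P3") == 0.0

    def test_identical_singletons(self):
        # 5 proteins, 2 in compartment 'A' of 5 annotations total
        loc = LocalizationTable(
            sets={
                "P1": frozenset({"A"}), "P2": frozenset({"A"}),
                "P3": frozenset({"B"}), "P4": frozenset({"B"}),
                "P5": frozenset({"B"}),
            },
            vocabulary=["A", "B"],
        )
        freq = location_frequency(loc)
        assert freq.scores["A"] == pytest.approx(0.4)
        assert colocalization_weight(freq, loc, "P1", "P2") == pytest.approx(0.4)

    def test_both_unannotated_zero(self, freq_loc):
        freq, loc = freq_loc
        assert colocalization_weight(freq, loc, "ghost1", "ghost2") == 0.0

    def test_random_sets_match_set_algebra_oracle(self):
        net, expr, loc, orth = random_instance(13, n=12, annotated=0.8)
        freq = None
        if loc.n_annotated:
            freq = location_frequency(loc)
        scores = oracles.sub_scores(loc.sets)
        for i, j in net.edges():
            u, v = net.node_ids[i], net.node_ids[j]
            got = colocalization_weight(freq, loc, u, v)
            want = oracles.colo_sub(
                scores, loc.compartments(u), loc.compartments(v)
            )
            assert got == pytest.approx(want, abs=1e-12)


class TestCLN:
    def test_all_unannotated_zero_layer(self, triangle):
        net, _ = triangle
        loc = LocalizationTable(sets={}, vocabulary=[])
        cln = build_cln(net, loc)
        assert cln.matrix.nnz == 0

    def test_single_edge_identical_singletons(self):
        net, ids = make_network(2, [(0, 1)])
        loc = LocalizationTable(
            sets={ids[0]: frozenset({"A"}), ids[1]: frozenset({"A"})},
            vocabulary=["A"],
        )
        cln = build_cln(net, loc)
        assert cln.matrix[0, 1] == pytest.approx(1.0)  # sub_score(A) = 1

    def test_random_instance_per_edge_oracle(self):
        net, expr, loc, orth = random_instance(17, n=14, annotated=0.7)
        cln = build_cln(net, loc)
        scores = oracles.sub_scores(loc.sets)
        for i, j in net.edges():
            want = oracles.colo_sub(
                scores,
                loc.compartments(net.node_ids[i]),
                loc.compartments(net.node_ids[j]),
            )
            assert cln.matrix[i, j] == pytest.approx(want, abs=1e-12)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_layers_symmetric_nonnegative_edge_supported(seed):
    """Every layer is symmetric, finite, >= 0, and supported only on E."""
    net, expr, loc, orth = random_instance(seed, n=10, coverage=0.8, annotated=0.8)
    adjacency = net.adjacency.toarray()
    for layer in (build_adn(net), build_cen(net, expr), build_cln(net, loc)):
        m = layer.matrix.toarray()
        assert np.allclose(m, m.T)
        assert np.all(np.isfinite(m)) and np.all(m >= 0)
        assert np.all(m[adjacency == 0] == 0)
        if layer.tag == "CLN":
            assert m.max() <= 1.0 + 1e-12
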