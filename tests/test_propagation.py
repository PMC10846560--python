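import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import netshort_oracle
from crosstalk.io import SeedSet
from crosstalk.propagation import (
    PropagationParams,
    ScoreTable,
    initial_scores,
    minmax_scale,
    netcombo,
    netscore,
    netshort,
    netzcore,
    rewire_preserving_degree,
    score_phenotype,
)


def seed_set(seeds, phenotype="P", category="CVD"):
    return SeedSet(phenotype, category, frozenset(seeds))


def assert_scaled(scores):
    values = sorted(scores.values())
    if all(v == values[0] for v in values):
        assert values[0] == 0.5
    else:
        assert values[0] == 0.0 and values[-1] == 1.0


class TestInitialScores:
    def test_seed_indicator(self):
        graph = nx.Graph([("A", "B"), ("B", "C")])
        assert initial_scores(graph, seed_set({"A"})) == {
            "A": 1.0, "B": 0.0, "C": 0.0
        }

    def test_all_seeds(self):
        graph = nx.Graph([("A", "B")])
        assert set(initial_scores(graph, seed_set({"A", "B"})).values()) == {1.0}

    def test_foreign_seed_rejected(self):
        graph = nx.Graph([("A", "B")])
        with pytest.raises(ValueError):
            initial_scores(graph, seed_set({"Z"}))


class TestMinmaxScale:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ({"A": 2.0, "B": 1.0, "C": 0.0}, {"A": 1.0, "B": 0.5, "C": 0.0}),
            ({"A": 7.0, "B": 7.0}, {"A": 0.5, "B": 0.5}),
            ({"A": -1.0, "B": 1.0}, {"A": 0.0, "B": 1.0}),
        ],
    )
    def test_examples(self, raw, expected):
        assert minmax_scale(raw) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            minmax_scale({"A": float("nan"), "B": 0.0})

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_range_property(self, values):
        scores = minmax_scale({str(i): v for i, v in enumerate(values)})
        assert_scaled(scores)


class TestNetshort:
    def test_hand_worked_path(self, tiny_path):
        # seed A: w(A,B)=1/2, w(B,C)=1; raw B=2, C=2/3, A=pinned max=2
        table = netshort(tiny_path, seed_set({"A"}))
        assert table.scores == {"A": 1.0, "B": 1.0, "C": 0.0}

    def test_two_seed_path_matches_oracle(self, tiny_path):
        table = netshort(tiny_path, seed_set({"A", "C"}))
        oracle = netshort_oracle(tiny_path, {"A", "C"})
        assert table.scores == pytest.approx(oracle, abs=1e-12)

    def test_isolated_node_scores_zero(self):
        graph = nx.Graph([("A", "B")])
        graph.add_node("X")
        table = netshort(graph, seed_set({"A"}))
        assert table.scores["X"] == 0.0

    def test_label_equivariance(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            graph = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
            graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
            if graph.number_of_edges() == 0:
                continue
            seeds = set(rng.choice(sorted(graph.nodes), size=2, replace=False))
            permutation = dict(
                zip(sorted(graph.nodes), rng.permutation(sorted(graph.nodes)))
            )
            relabeled = nx.relabel_nodes(graph, permutation)
            base = netshort(graph, seed_set(seeds)).scores
            mapped = netshort(
                relabeled, seed_set({permutation[s] for s in seeds})
            ).scores
            for node in graph.nodes:
                assert mapped[permutation[node]] == pytest.approx(
                    base[node], abs=1e-12
                )


class TestRewire:
    def test_degree_sequence_preserved(self):
        graph = nx.barabasi_albert_graph(40, 2, seed=1)
        rewired = rewire_preserving_degree(graph, 10, rng_seed=3)
        assert dict(rewired.degree()) == dict(graph.degree())
        assert nx.number_of_selfloops(rewired) == 0

    def test_c4_rewiring_stays_2_regular(self):
        # all simple 2-regular graphs on 4 labeled nodes are 4-cycles
        graph = nx.cycle_graph(4)
        for trial in range(10):
            rewired = rewire_preserving_degree(graph, 10, rng_seed=trial)
            assert sorted(d for _, d in rewired.degree()) == [2, 2, 2, 2]
            assert nx.is_connected(rewired)

    def test_deterministic_per_seed(self):
        graph = nx.barabasi_albert_graph(30, 2, seed=1)
        g1 = rewire_preserving_degree(graph, 10, rng_seed=9)
        g2 = rewire_preserving_degree(graph, 10, rng_seed=9)
        assert nx.utils.graphs_equal(g1, g2)

    def test_unswappable_graph_returned_unchanged(self):
        graph = nx.Graph([("A", "B")])
        rewired = rewire_preserving_degree(graph, 10, rng_seed=0)
        assert nx.utils.graphs_equal(rewired, graph)


def all_degree_matched_graphs(graph):
    """Every labeled simple graph with the same per-node degrees (brute)."""
    nodes = sorted(graph.nodes)
    degrees = {v: graph.degree(v) for v in nodes}
    possible = list(itertools.combinations(nodes, 2))
    matched = []
    n_edges = graph.number_of_edges()
    for edges in itertools.combinations(possible, n_edges):
        candidate = nx.Graph()
        candidate.add_nodes_from(nodes)
        candidate.add_edges_from(edges)
        if {v: candidate.degree(v) for v in nodes} == degrees:
            matched.append(candidate)
    return matched


class TestNetzcore:
    def test_star_neighbor_averaging(self):
        # center seed, one round: leaves average to 1, center averages to 0;
        # with a rigid null (stars only rewire to stars) z=0 -> uniform 0.5
        graph = nx.star_graph(3)
        graph = nx.relabel_nodes(graph, {0: "C", 1: "L1", 2: "L2", 3: "L3"})
        params = PropagationParams(rng_seed=1, iterations=1, null_replicates=4)
        nulls = all_degree_matched_graphs(graph)
        table = netzcore(graph, seed_set({"C"}), params, null_graphs=nulls)
        assert set(table.scores.values()) == {0.5}

    def test_identical_nulls_give_uniform_half(self):
        graph = nx.cycle_graph(5)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        params = PropagationParams(rng_seed=1, null_replicates=3)
        table = netzcore(
            graph, seed_set({"N0"}), params, null_graphs=[graph, graph, graph]
        )
        assert set(table.scores.values()) == {0.5}

    def test_automorphic_nodes_equal_under_exhaustive_nulls(self):
        graph = nx.cycle_graph(4)
        graph = nx.relabel_nodes(graph, {0: "A", 1: "B", 2: "C", 3: "D"})
        params = PropagationParams(rng_seed=1, iterations=2, null_replicates=3)
        nulls = all_degree_matched_graphs(graph)
        table = netzcore(graph, seed_set({"A"}), params, null_graphs=nulls)
        # B and D are exchanged by the automorphism fixing the seed A
        assert table.scores["B"] == pytest.approx(table.scores["D"], abs=1e-12)

    def test_scaled_output(self):
        graph = nx.barabasi_albert_graph(30, 2, seed=2)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        params = PropagationParams(rng_seed=4, null_replicates=5)
        table = netzcore(graph, seed_set({"N0", "N5"}), params)
        assert_scaled(table.scores)


class TestNetscore:
    def test_zero_damping_reproduces_seed_indicator(self):
        graph = nx.path_graph(["A", "B", "C", "D"])
        params = PropagationParams(rng_seed=1, damping=0.0)
        table = netscore(graph, seed_set({"A"}), params)
        assert table.scores == {"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0}

    def test_star_single_round_messages(self):
        # center (degree 3) seeds each leaf with 1/3; center receives 0
        graph = nx.star_graph(3)
        graph = nx.relabel_nodes(graph, {0: "C", 1: "L1", 2: "L2", 3: "L3"})
        params = PropagationParams(
            rng_seed=1, damping=1.0, iterations=1, repetitions=1
        )
        table = netscore(graph, seed_set({"C"}), params)
        # raw: leaves 1/3, center 0 -> scaled: leaves 1, center 0
        assert table.scores == {"C": 0.0, "L1": 1.0, "L2": 1.0, "L3": 1.0}

    def test_repetitions_compose(self):
        graph = nx.barabasi_albert_graph(25, 2, seed=3)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        seeds = seed_set({"N0", "N3"})
        two = netscore(
            graph, seeds, PropagationParams(rng_seed=1, repetitions=2)
        ).scores
        # applying the one-repetition operator twice with re-based scores
        once = netscore(
            graph, seeds, PropagationParams(rng_seed=1, repetitions=1)
        ).scores
        rebased = ScoreTable("P", "netscore", once)
        # rebasing means: use `once` as the new base indicator
        graph_nodes = sorted(graph.nodes)
        lam, iters = 0.5, 2
        import numpy as np
        adjacency = nx.to_scipy_sparse_array(graph, nodelist=graph_nodes)
        deg = np.asarray(adjacency.sum(axis=1)).ravel()
        base = np.array([rebased.scores[v] for v in graph_nodes])
        s = base.copy()
        for _ in range(iters):
            s = (1 - lam) * base + lam * (adjacency @ (s / deg))
        lo, hi = s.min(), s.max()
        manual = dict(zip(graph_nodes, (s - lo) / (hi - lo)))
        assert two == pytest.approx(manual, abs=1e-12)

    def test_label_equivariance(self):
        rng = np.random.default_rng(11)
        graph = nx.gnp_random_graph(9, 0.35, seed=17)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        seeds = {"N1", "N4"}
        permutation = dict(
            zip(sorted(graph.nodes), rng.permutation(sorted(graph.nodes)))
        )
        params = PropagationParams(rng_seed=1)
        base = netscore(graph, seed_set(seeds), params).scores
        mapped = netscore(
            nx.relabel_nodes(graph, permutation),
            seed_set({permutation[s] for s in seeds}),
            params,
        ).scores
        for node in graph.nodes:
            assert mapped[permutation[node]] == pytest.approx(base[node], abs=1e-12)


class TestNetcombo:
    def test_identical_tables_scale_through(self):
        scores = {"A": 0.2, "B": 0.9, "C": 0.4}
        tables = [ScoreTable("P", "netscore", scores) for _ in range(3)]
        combined = netcombo(*tables)
        assert combined.scores == pytest.approx(minmax_scale(scores))

    def test_constant_table_contributes_zero(self):
        t_const = ScoreTable("P", "netshort", {"A": 0.5, "B": 0.5})
        t1 = ScoreTable("P", "netscore", {"A": 0.0, "B": 1.0})
        t2 = ScoreTable("P", "netzcore", {"A": 0.2, "B": 0.8})
        combined = netcombo(t1, t2, t_const)
        assert combined.scores == {"A": 0.0, "B": 1.0}

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        nodes = [f"N{i}" for i in range(5)]
        raw = rng.random((3, 5))
        tables = [
            ScoreTable("P", alg, dict(zip(nodes, row)))
            for alg, row in zip(("netscore", "netzcore", "netshort"), raw)
        ]
        combined = netcombo(*tables)
        standardized = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(
            axis=1, keepdims=True
        )
        mean = standardized.mean(axis=0)
        expected = (mean - mean.min()) / (mean.max() - mean.min())
        assert combined.scores == pytest.approx(dict(zip(nodes, expected)))

    def test_domain_mismatch_rejected(self):
        t1 = ScoreTable("P", "netscore", {"A": 0.1, "B": 0.2})
        t2 = ScoreTable("P", "netzcore", {"A": 0.1, "C": 0.2})
        with pytest.raises(ValueError):
            netcombo(t1, t2, t1)


class TestScorePhenotype:
    def test_consensus_properties(self):
        graph = nx.barabasi_albert_graph(60, 2, seed=8)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        seeds = seed_set({"N0", "N1", "N2"})
        params = PropagationParams(rng_seed=21, null_replicates=10)
        table = score_phenotype(graph, seeds, params)
        assert table.algorithm == "netcombo"
        assert set(table.scores) == set(graph.nodes)
        assert_scaled(table.scores)

    def test_deterministic_for_fixed_seed(self):
        graph = nx.barabasi_albert_graph(40, 2, seed=8)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        seeds = seed_set({"N0", "N4"})
        params = PropagationParams(rng_seed=13, null_replicates=6)
        t1 = score_phenotype(graph, seeds, params)
        t2 = score_phenotype(graph, seeds, params)
        assert t1.scores == t2.scores


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"repetitions": 0},
            {"iterations": 0},
            {"damping": 1.5},
            {"null_replicates": 0},
            {"rewire_swaps_per_edge": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PropagationParams(rng_seed=1, **kwargs)
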