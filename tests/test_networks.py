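from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, rankdata

from paracong.io import CommunityTable
from paracong.networks import (
    bootstrap_pseudo_p,
    build_network,
    classify_roles,
    correlation_matrix,
    greedy_modularity,
    network_stats,
    zi_pi,
)

from conftest import random_table


class TestCorrelationMatrix:
    def test_unit_diagonal_and_duplicate_rows(self, rng):
        data = pd.DataFrame(
            rng.integers(1, 30, size=(4, 6)),
            index=["a", "b", "c", "d"],
            columns=[f"s{i}" for i in range(6)],
        )
        data.loc["b"] = data.loc["a"]  # identical count vectors
        r = correlation_matrix(CommunityTable(data))
        np.testing.assert_allclose(np.diag(r), 1.0)
        # identical counts give identical relative abundances -> rho = 1
        assert r.at["a", "b"] == pytest.approx(1.0)

    def test_spearman_matches_rank_pearson_oracle(self, rng):
        table = random_table([f"t{i}" for i in range(5)], 8, rng)
        r = correlation_matrix(table)
        rel = table.relative_abundance().to_numpy()
        for i, j in combinations(range(5), 2):
            ri = rankdata(rel[i])
            rj = rankdata(rel[j])
            expected = np.corrcoef(ri, rj)[0, 1]
            assert r.iat[i, j] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_taxon_excluded(self, rng):
        data = pd.DataFrame(
            rng.integers(1, 9, size=(3, 5)),
            index=["a", "b", "flat"],
            columns=[f"s{i}" for i in range(5)],
        )
        rel = data / data.sum(axis=0)
        # engineer a constant relative abundance row
        data.loc["flat"] = (data.drop(index="flat").sum(axis=0)).astype(int)
        table = CommunityTable(data)
        rel = table.relative_abundance()
        if rel.loc["flat"].nunique() == 1:
            r = correlation_matrix(table)
            assert "flat" not in r.index

    def test_too_few_samples_rejected(self, rng):
        table = random_table(["a", "b"], 3, rng)
        with pytest.raises(ValueError, match="4 samples"):
            correlation_matrix(table)

    def test_sparcc_recovers_strong_positive_pair(self, rng):
        # two taxa driven by the same latent log-signal should come out
        # strongly positively correlated under basic SparCC
        n = 40
        latent = rng.normal(size=n)
        counts = np.vstack(
            [
                np.exp(4 + 1.5 * latent + rng.normal(0, 0.1, n)),
                np.exp(4 + 1.5 * latent + rng.normal(0, 0.1, n)),
            ]
            + [np.exp(rng.normal(4, 1, n)) for _ in range(8)]
        ).round().astype(int)
        table = CommunityTable(
            pd.DataFrame(counts, index=[f"t{i}" for i in range(10)],
                         columns=[f"s{j}" for j in range(n)])
        )
        r = correlation_matrix(table, method="sparcc")
        assert r.at["t0", "t1"] > 0.6
        assert np.abs(r.to_numpy()).max() <= 1.0 + 1e-12


class TestBootstrapPseudoP:
    def test_perfect_pair_is_significant(self, rng):
        n = 20
        x = np.arange(1, n + 1)
        counts = np.vstack([x, 2 * x] + [rng.integers(1, 50, n) for _ in range(4)])
        table = CommunityTable(
            pd.DataFrame(counts, index=[f"t{i}" for i in range(6)],
                         columns=[f"s{j}" for j in range(n)])
        )
        p = bootstrap_pseudo_p(table, n_boot=999, seed=1)
        assert p.at["t0", "t1"] <= 0.01

    def test_null_p_roughly_uniform(self, rng):
        # independent taxa; enough of them that compositional closure is
        # negligible relative to the null sd of r
        pvals = []
        for rep in range(3):
            counts = rng.poisson(100, size=(20, 12))
            table = CommunityTable(
                pd.DataFrame(counts, index=[f"t{i}" for i in range(20)],
                             columns=[f"s{j}" for j in range(12)])
            )
            p = bootstrap_pseudo_p(table, n_boot=199, seed=rep)
            pvals.extend(p.to_numpy()[np.triu_indices(20, k=1)])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_deterministic_and_bounds(self, rng):
        table = random_table([f"t{i}" for i in range(4)], 8, rng)
        p1 = bootstrap_pseudo_p(table, n_boot=99, seed=4)
        p2 = bootstrap_pseudo_p(table, n_boot=99, seed=4)
        pd.testing.assert_frame_equal(p1, p2)
        assert ((p1.to_numpy() > 0) & (p1.to_numpy() <= 1)).all()

    def test_zero_bootstraps_rejected(self, rng):
        table = random_table(["a", "b"], 6, rng)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_pseudo_p(table, n_boot=0)


def toy_matrices():
    ids = ["a", "b", "c", "d"]
    r = pd.DataFrame(np.eye(4), index=ids, columns=ids)
    p = pd.DataFrame(np.ones((4, 4)), index=ids, columns=ids)
    # qualifying pairs: (a,b) and (c,d)
    for i, j, rv, pv in [(0, 1, 0.9, 0.001), (2, 3, -0.7, 0.01),
                         (0, 2, 0.6, 0.001),   # |r| at threshold -> excluded
                         (1, 3, 0.9, 0.05)]:   # p at threshold -> excluded
        r.iat[i, j] = r.iat[j, i] = rv
        p.iat[i, j] = p.iat[j, i] = pv
    return r, p


class TestBuildNetwork:
    def test_strict_threshold_semantics(self):
        r, p = toy_matrices()
        g = build_network(r, p)
        assert set(map(frozenset, g.edges())) == {
            frozenset({"a", "b"}),
            frozenset({"c", "d"}),
        }
        assert g.number_of_nodes() == 4  # isolated nodes retained

    def test_complete_graph_when_everything_qualifies(self):
        ids = list("abcde")
        r = pd.DataFrame(np.ones((5, 5)), index=ids, columns=ids)
        p = pd.DataFrame(np.zeros((5, 5)), index=ids, columns=ids)
        g = build_network(r, p)
        assert g.number_of_edges() == 10

    def test_asymmetric_input_rejected(self):
        r, p = toy_matrices()
        r.iat[0, 1] = 0.123
        with pytest.raises(ValueError, match="asymmetric"):
            build_network(r, p)

    def test_invariant_to_taxon_reordering(self):
        r, p = toy_matrices()
        order = ["d", "b", "a", "c"]
        g1 = build_network(r, p)
        g2 = build_network(r.loc[order, order], p.loc[order, order])
        assert set(map(frozenset, g1.edges())) == set(map(frozenset, g2.edges()))


def two_cliques_graph():
    g = nx.Graph()
    left = [f"L{i}" for i in range(6)]
    right = [f"R{i}" for i in range(6)]
    for group in (left, right):
        g.add_edges_from(combinations(group, 2))
    g.add_edge("L0", "R0")
    return g, left, right


class TestGreedyModularity:
    def test_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        modules, q = greedy_modularity(g)
        assert modules["a"] == modules["b"] == modules["c"]
        assert modules["x"] == modules["y"] == modules["z"]
        assert modules["a"] != modules["x"]

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(5)
        modules, _ = greedy_modularity(g)
        assert len(set(modules.values())) == 1

    def test_two_clique_partition_matches_exhaustive_search(self):
        g, left, right = two_cliques_graph()
        modules, q = greedy_modularity(g)
        # brute-force oracle over all 2-partitions (by subset enumeration)
        nodes = sorted(g.nodes())
        best_q, best_partition = -1.0, None
        for mask in range(1, 2 ** (len(nodes) - 1)):
            part_a = {nodes[i] for i in range(len(nodes)) if (mask >> i) & 1}
            part_a.add(nodes[-1])
            part_b = set(nodes) - part_a
            if not part_b:
                continue
            q_val = nx.community.modularity(g, [part_a, part_b])
            if q_val > best_q:
                best_q, best_partition = q_val, (part_a, part_b)
        found = [
            {n for n in nodes if modules[n] == m} for m in set(modules.values())
        ]
        assert len(found) == 2
        assert set(map(frozenset, found)) == set(map(frozenset, best_partition))
        assert q == pytest.approx(best_q, abs=1e-12)

    def test_edgeless_graph_singleton_modules(self):
        g = nx.empty_graph(4)
        modules, q = greedy_modularity(g)
        assert len(set(modules.values())) == 4
        assert q == 0.0


def two_module_toy():
    """10-node, 2-module graph with hand-computable Zi/Pi."""
    g = nx.Graph()
    m1 = ["a", "b", "c", "d", "e"]
    m2 = ["f", "g", "h", "i", "j"]
    # module 1: hub 'a' connected to all of m1, no other edges inside
    g.add_nodes_from(m1 + m2)
    g.add_edges_from(("a", n) for n in m1[1:])
    # module 2: 5-cycle
    g.add_edges_from(zip(m2, m2[1:] + m2[:1]))
    # connectors: b-f
    g.add_edge("b", "f")
    modules = {n: 0 for n in m1} | {n: 1 for n in m2}
    return g, modules


class TestZiPi:
    def test_hand_computed_values(self):
        g, modules = two_module_toy()
        zipi = zi_pi(g, modules)
        # module 1 within-degrees: a=4, others=1 -> mean 1.6, sd (pop) of
        # [4,1,1,1,1]: var = (5.76+0.36*4)/5 = 1.44, sd = 1.2
        assert zipi.at["a", "Zi"] == pytest.approx((4 - 1.6) / 1.2)
        assert zipi.at["c", "Zi"] == pytest.approx((1 - 1.6) / 1.2)
        # module 2 is a 5-cycle: all within-degrees 2 except f has +1 external
        assert zipi.at["g", "Zi"] == pytest.approx(0.0)  # sd 0 convention
        # Pi: node b has degree 2, one edge in each module -> 1 - 2*(1/2)^2
        assert zipi.at["b", "Pi"] == pytest.approx(0.5)
        # node a all edges internal
        assert zipi.at["a", "Pi"] == pytest.approx(0.0)
        # node f: degree 3, 2 internal 1 external -> 1 - (4/9 + 1/9)
        assert zipi.at["f", "Pi"] == pytest.approx(1 - 5 / 9)

    def test_zi_sums_to_zero_within_nondegenerate_module(self):
        g, modules = two_module_toy()
        zipi = zi_pi(g, modules)
        module0 = zipi[zipi["module"] == 0]
        assert module0["Zi"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_pi_in_unit_interval(self, rng):
        g = nx.gnp_random_graph(25, 0.15, seed=7)
        modules, _ = greedy_modularity(g)
        zipi = zi_pi(g, modules)
        assert zipi["Pi"].between(0, 1).all()

    def test_isolated_node_pi_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        g.add_edge("x", "y")
        g.add_node("lonely")
        zipi = zi_pi(g, {"x": 0, "y": 0, "lonely": 1})
        assert zipi.at["lonely", "Pi"] == 0.0

    def test_unassigned_node_rejected(self):
        g, modules = two_module_toy()
        del modules["a"]
        with pytest.raises(ValueError, match="module"):
            zi_pi(g, modules)


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "zi, pi, role",
        [
            (0.0, 0.0, "peripheral"),
            (0.0, 0.7, "connector"),
            (3.0, 0.1, "module hub"),
            (3.0, 0.7, "network hub"),
            (2.5, 0.62, "network hub"),  # inclusive boundaries
            (2.4999, 0.6199, "peripheral"),
        ],
    )
    def test_role_assignment(self, zi, pi, role):
        df = pd.DataFrame({"Zi": [zi], "Pi": [pi]}, index=["n"])
        assert classify_roles(df).at["n"] == role


class TestNetworkStats:
    def test_path_graph_closed_form(self):
        g = nx.path_graph(["a", "b", "c"])
        stats = network_stats(g)
        assert stats.avg_degree == pytest.approx(4 / 3)
        assert stats.avg_path_distance == pytest.approx((1 + 1 + 2) / 3)
        assert stats.degree_distribution == {1: 2, 2: 1}

    def test_edgeless_graph_gd_undefined(self):
        stats = network_stats(nx.empty_graph(5))
        assert stats.avg_degree == 0.0
        assert stats.avg_path_distance is None

    def test_gd_matches_bfs_oracle(self, rng):
        g = nx.gnp_random_graph(30, 0.12, seed=11)
        stats = network_stats(g)

        def bfs_lengths(start):
            seen = {start: 0}
            frontier = [start]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in g.neighbors(u):
                        if v not in seen:
                            seen[v] = seen[u] + 1
                            nxt.append(v)
                frontier = nxt
            return seen

        total, pairs = 0, 0
        for node in g.nodes():
            for other, dist in bfs_lengths(node).items():
                if dist > 0:
                    total += dist
                    pairs += 1
        assert stats.avg_path_distance == pytest.approx(total / pairs)
        assert stats.n_unreachable_pairs == 30 * 29 - pairs
        assert sum(stats.degree_distribution.values()) == 30
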