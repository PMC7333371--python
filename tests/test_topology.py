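"""Centralities, IC overrepresentation, power-law fit, ranking, modules."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from senonet.topology import (
    compute_topology,
    detect_modules,
    fit_power_law,
    ic_pvalues,
    network_density,
    rank_candidates,
)


class TestCentralities:
    def test_star_closed_forms(self, star5):
        report = compute_topology(star5, seeds=set())
        assert report.at["c", "bc"] == pytest.approx(1.0)
        assert report.at["c", "cc"] == pytest.approx(1.0)
        for leaf in ["l1", "l2", "l3", "l4"]:
            assert report.at[leaf, "bc"] == 0.0

    def test_path_closed_forms(self, path3):
        report = compute_topology(path3, seeds=set())
        assert report.at["m", "bc"] == pytest.approx(1.0)
        assert report.at["a", "bc"] == 0.0
        assert report.at["a", "cc"] == pytest.approx(2 / 3)
        assert report.at["m", "local_cc"] == 0.0

    def test_triangle_clustering(self):
        report = compute_topology(nx.complete_graph(["a", "b", "c"]), seeds=set())
        assert (report["local_cc"] == 1.0).all()

    def test_degree_sum_is_twice_edges(self):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        report = compute_topology(g, seeds=set())
        assert report["degree"].sum() == 2 * g.number_of_edges()

    def test_centralities_bounded(self):
        g = nx.gnp_random_graph(40, 0.1, seed=1)
        report = compute_topology(g, seeds=set())
        for col in ("bc", "cc", "local_cc"):
            assert report[col].between(0, 1).all()

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            compute_topology(nx.Graph(), seeds=set())


class TestDensity:
    def test_complete_graph(self):
        assert network_density(nx.complete_graph(4)) == 1.0

    def test_path(self, path3):
        assert network_density(path3) == pytest.approx(2 / 3)

    def test_six_node_six_edge(self):
        g = nx.cycle_graph(6)
        assert network_density(g) == pytest.approx(0.4)


class TestPowerLaw:
    def test_exact_power_law_recovered(self):
        # a forest realizing degree frequencies f(k) = 64 k^-2 exactly:
        # one 8-star, four 4-stars, sixteen 3-paths, four isolated edges
        # gives histogram {1: 64, 2: 16, 4: 4, 8: 1}
        g = nx.Graph()
        g.add_edges_from((f"h_{i}", "hub") for i in range(8))
        for s in range(4):
            g.add_edges_from((f"s{s}_{i}", f"center{s}") for i in range(4))
        for p in range(16):
            g.add_edges_from([(f"p{p}_a", f"p{p}_m"), (f"p{p}_m", f"p{p}_b")])
        g.add_edges_from((f"e{i}_a", f"e{i}_b") for i in range(4))
        hist = dict(zip(*np.unique([d for _, d in g.degree()], return_counts=True)))
        assert hist == {1: 64, 2: 16, 4: 4, 8: 1}
        fit = fit_power_law(g)
        assert fit.exponent == pytest.approx(-2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficient == pytest.approx(64.0, rel=1e-9)

    def test_regular_graph_degenerate(self):
        with pytest.raises(ValueError):
            fit_power_law(nx.cycle_graph(10))

    def test_preferential_attachment_negative_slope(self):
        from senonet.synthetic import gen_scalefree_graph

        g, _ = gen_scalefree_graph(300, 3, 0.1, False, seed=5)
        assert fit_power_law(g).exponent < 0


class TestIC:
    def test_three_seed_neighbor_enumeration(self):
        # node n1 adjacent to exactly the three seeds in a 5-node component:
        # draw 3 of 4 other nodes (3 seeds) -> P(X >= 3) = C(3,3)C(1,0)/C(4,3)
        net = nx.Graph([("s1", "n1"), ("s2", "n1"), ("s3", "n1"), ("s1", "n2")])
        ic = ic_pvalues(net, {"s1", "s2", "s3"})
        assert ic.at["n1", "ic_p"] == pytest.approx(0.25)

    def test_zero_seed_neighbors_p_one(self):
        net = nx.Graph([("s1", "a"), ("a", "b")])
        ic = ic_pvalues(net, {"s1"})
        assert ic.at["b", "ic_p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=trial)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        nodes = sorted(g.nodes)
        seeds = set(rng.choice(nodes, size=int(rng.integers(1, n + 1)), replace=False))
        result = ic_pvalues(g, seeds)
        for comp in nx.connected_components(g):
            for v in comp:
                others = sorted(comp - {v})
                k = g.degree(v)
                x = len(set(g.neighbors(v)) & seeds)
                draws = list(itertools.combinations(others, k))
                brute = sum(
                    len(set(sub) & seeds) >= x for sub in draws
                ) / len(draws)
                assert result.at[v, "ic_p"] == pytest.approx(brute, abs=1e-12)

    def test_bh_adjustment_dominates_raw(self):
        g = nx.gnp_random_graph(15, 0.4, seed=2)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        ic = ic_pvalues(g, {"v0", "v1", "v2"})
        assert (ic["ic_p_adj"] >= ic["ic_p"] - 1e-12).all()

    def test_empty_seed_set_rejected(self, star5):
        with pytest.raises(ValueError):
            ic_pvalues(star5, set())

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_hub_has_top_adjusted_ic(self, seed):
        from senonet.synthetic import gen_scalefree_graph

        g, seeds = gen_scalefree_graph(150, 3, 0.1, True, seed=seed)
        ic = ic_pvalues(g, seeds)
        assert ic["ic_p_adj"].idxmin() == "planted_hub"


def _report(rows: dict[str, dict]) -> pd.DataFrame:
    base = {
        "degree": 1, "bc": 0.0, "cc": 0.1, "local_cc": 0.0,
        "ic_p": 1.0, "ic_p_adj": 1.0, "is_seed": False,
    }
    return pd.DataFrame(
        {node: {**base, **vals} for node, vals in rows.items()}
    ).T.infer_objects()


class TestRankCandidates:
    def _background(self, n=200):
        rng = np.random.default_rng(0)
        return _report(
            {
                f"bg{i}": {
                    "degree": int(rng.integers(1, 5)),
                    "bc": rng.uniform(0, 0.01),
                    "cc": rng.uniform(0.05, 0.1),
                }
                for i in range(n)
            }
        )

    def test_double_top_membership_qualifies(self):
        report = self._background()
        report.loc["X"] = {
            "degree": 99, "bc": 0.9, "cc": 0.01, "local_cc": 0,
            "ic_p": 1.0, "ic_p_adj": 1.0, "is_seed": False,
        }
        out = rank_candidates(report)
        assert "X" in set(out["node"])

    def test_single_membership_without_ic_excluded(self):
        report = self._background()
        report.loc["Y"] = {
            "degree": 99, "bc": 0.0, "cc": 0.01, "local_cc": 0,
            "ic_p": 1.0, "ic_p_adj": 1.0, "is_seed": False,
        }
        out = rank_candidates(report)
        assert "Y" not in set(out["node"])

    def test_significant_ic_plus_membership_qualifies(self):
        report = self._background()
        report.loc["Z"] = {
            "degree": 99, "bc": 0.0, "cc": 0.01, "local_cc": 0,
            "ic_p": 0.001, "ic_p_adj": 0.01, "is_seed": False,
        }
        out = rank_candidates(report)
        assert "Z" in set(out["node"])

    def test_novel_only_drops_seeds(self):
        report = self._background()
        report.loc["S"] = {
            "degree": 99, "bc": 0.9, "cc": 0.01, "local_cc": 0,
            "ic_p": 1.0, "ic_p_adj": 1.0, "is_seed": True,
        }
        assert "S" in set(rank_candidates(report)["node"])
        assert "S" not in set(rank_candidates(report, novel_only=True)["node"])

    def test_relabeling_invariance(self):
        report = self._background(50)
        report.loc["X"] = {
            "degree": 99, "bc": 0.9, "cc": 0.01, "local_cc": 0,
            "ic_p": 1.0, "ic_p_adj": 1.0, "is_seed": False,
        }
        renamed = report.rename(index=lambda s: f"re_{s}")
        out = set(rank_candidates(report)["node"])
        out2 = set(rank_candidates(renamed)["node"])
        assert {f"re_{n}" for n in out} == out2

    def test_bad_tier_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates(self._background(), top_tier=0.0)


class TestModules:
    def test_two_cliques_with_bridge(self):
        g = nx.Graph()
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        g.add_edges_from(itertools.combinations(a, 2))
        g.add_edges_from(itertools.combinations(b, 2))
        g.add_edge("a0", "b0")
        part = detect_modules(g)
        assert sorted(part.sizes.values()) == [5, 5]
        groups = {}
        for node, mid in part.module_of.items():
            groups.setdefault(mid, set()).add(node)
        assert set(map(frozenset, groups.values())) == {frozenset(a), frozenset(b)}

    def test_single_clique_single_module(self):
        g = nx.complete_graph(6)
        part = detect_modules(g)
        assert part.sizes == {1: 6} and not part.unassigned

    def test_min_size_filter_can_empty_partition(self):
        g = nx.complete_graph(5)
        part = detect_modules(g, min_size_fraction=2.0)
        assert part.module_of == {} and part.unassigned == set(g.nodes)

    def test_disjoint_cliques_recovered(self):
        g = nx.Graph()
        cliques = [[f"c{k}_{i}" for i in range(4)] for k in range(3)]
        for c in cliques:
            g.add_edges_from(itertools.combinations(c, 2))
        part = detect_modules(g)
        groups = {}
        for node, mid in part.module_of.items():
            groups.setdefault(mid, set()).add(node)
        assert set(map(frozenset, groups.values())) == set(map(frozenset, cliques))

    def test_bad_lambda_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(nx.complete_graph(4), lam=0)
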