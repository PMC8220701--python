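"""Bounded k-best path search, greedy selection, stability, penalty sweep."""

import itertools

import numpy as np
import pytest

from conftest import brute_force_paths, random_weighted_network

from suppnet import PipelineConfig
from suppnet.data import Subnetwork, SyntheticTruth, WeightedNetwork
from suppnet.scoring import COST_EPS
from suppnet.subnet import (
    enumerate_paths,
    jaccard,
    k_best_paths,
    recover_planted,
    select_subnetwork,
    stability,
    sweep_and_finalize,
)


def _net(edges, weights=None):
    net = WeightedNetwork()
    for u, v, t in edges:
        net.add_edge(u, v, t)
    w = {e: 0.5 for e in net.edges()}
    if weights:
        w.update(weights)
    net.set_weights(w)
    return net


class TestKBestPaths:
    def test_single_chain(self):
        net = _net([("s", "a", "regulatory"), ("a", "t", "regulatory")])
        out = k_best_paths(net, "s", {"t"}, k=5, max_len=4, penalty_c=1.0)
        assert list(out) == ["t"]
        (path,) = out["t"]
        assert path.nodes == ("s", "a", "t")
        assert path.cost(1.0) == pytest.approx(2 * (0.5 + COST_EPS))

    def test_direction_respected(self):
        net = _net([("a", "s", "regulatory"), ("s", "t", "ppi")])
        out = k_best_paths(net, "s", {"a", "t"}, k=5, max_len=4)
        assert "a" not in out       # regulatory edge points the wrong way
        assert "t" in out           # ppi traversable both ways
        back = k_best_paths(net, "t", {"s"}, k=5, max_len=4)
        assert back["s"][0].nodes == ("t", "s")

    def test_diamond_ordered_by_cost(self):
        net = _net(
            [("s", "a", "regulatory"), ("a", "t", "regulatory"),
             ("s", "b", "regulatory"), ("b", "t", "regulatory")],
            weights={("s", "a", "regulatory"): 0.9,
                     ("a", "t", "regulatory"): 0.9,
                     ("s", "b", "regulatory"): 0.1,
                     ("b", "t", "regulatory"): 0.1})
        out = k_best_paths(net, "s", {"t"}, k=5, max_len=4, penalty_c=1.0)
        assert [p.nodes for p in out["t"]] == [("s", "a", "t"), ("s", "b", "t")]

    def test_missing_seed_skipped(self):
        net = _net([("a", "b", "ppi")])
        assert k_best_paths(net, "zz", {"a"}, k=3, max_len=4) == {}

    @pytest.mark.parametrize("trial", range(0, 200, 10))
    def test_matches_brute_force_enumeration(self, trial):
        """k-best equals exhaustive enumeration on random <=7-node graphs."""
        rng = np.random.default_rng(trial)
        for sub in range(10):
            net = random_weighted_network(
                rng, n_nodes=int(rng.integers(4, 8)),
                n_edges=int(rng.integers(4, 13)))
            nodes = sorted(net.nodes)
            seed = nodes[int(rng.integers(len(nodes)))]
            targets = set(rng.choice(nodes, size=2, replace=False)) - {seed}
            c = float(rng.uniform(0.1, 5.0))
            k = int(rng.integers(1, 6))
            got = k_best_paths(net, seed, targets, k=k, max_len=4, penalty_c=c)
            expected = brute_force_paths(net, seed, targets, 4, c)
            assert set(got) == set(expected)
            for t in expected:
                want = [(round(cost, 9), n) for cost, _l, n in expected[t][:k]]
                have = [(round(p.cost(c), 9), p.nodes) for p in got[t]]
                assert have == want


class TestSelectSubnetwork:
    def _pool(self, net, seeds, c=1.0):
        pool = enumerate_paths(net, seeds, max_len=4)
        return pool.candidates(c, k=50), pool.edge_omw

    def test_two_seeds_one_path(self):
        net = _net([("s", "a", "ppi"), ("a", "t", "ppi")],
                   weights={("a", "s", "ppi"): 0.9, ("a", "t", "ppi"): 0.9})
        cands, omw = self._pool(net, {"s", "t"})
        sub = select_subnetwork(cands, {"s", "t"}, 1.0, omw)
        assert sub.connected_seeds == {"s", "t"}
        assert len(sub.edges) == 2

    def test_cheap_path_beats_long_path(self):
        net = _net(
            [("s", "a", "ppi"), ("a", "t", "ppi"),
             ("s", "b", "ppi"), ("b", "c", "ppi"), ("c", "d", "ppi"),
             ("d", "t", "ppi")],
            weights={("a", "s", "ppi"): 0.95, ("a", "t", "ppi"): 0.95})
        cands, omw = self._pool(net, {"s", "t"})
        sub = select_subnetwork(cands, {"s", "t"}, 1.0, omw)
        assert sub.nodes == {"s", "a", "t"}

    def test_empty_candidates_valid(self):
        sub = select_subnetwork([], {"s", "t"}, 1.0, {})
        assert sub.edges == set() and sub.connected_seeds == set()

    def test_greedy_near_exhaustive_optimum(self):
        """Greedy score within a factor of the best over all path subsets."""
        rng = np.random.default_rng(42)
        worst = 1.0
        for _ in range(25):
            net = random_weighted_network(rng, n_nodes=7,
                                          n_edges=int(rng.integers(6, 14)))
            nodes = sorted(net.nodes)
            seeds = set(rng.choice(nodes, size=int(rng.integers(2, 6)),
                                   replace=False).tolist())
            pool = enumerate_paths(net, seeds, max_len=4)
            c = float(rng.uniform(0.2, 2.0))
            cands = pool.candidates(c, k=2)[:12]
            sub = select_subnetwork(cands, seeds, c, pool.edge_omw)
            best = 0.0
            for r in range(len(cands) + 1):
                for combo in itertools.combinations(cands, r):
                    edges = set().union(*(p.edges for p in combo)) if combo \
                        else set()
                    connected = set().union(
                        *( {n for n in p.nodes if n in seeds} for p in combo)
                    ) if combo else set()
                    cost = sum(c * pool.edge_omw[e] + COST_EPS for e in edges)
                    best = max(best, len(connected) - cost)
            if best > 0:
                worst = min(worst, (max(sub.selection_score, 0.0)) / best)
            else:
                assert sub.selection_score <= 1e-9
        assert worst >= 0.5, f"greedy/optimal ratio dropped to {worst:.3f}"


class TestStability:
    def test_deterministic_star_is_fully_stable(self):
        edges = [(f"s{i}", "hub", "ppi") for i in range(6)]
        net = _net(edges, weights={e: 0.99 for e in _net(edges).edges()})
        seeds = {f"s{i}" for i in range(6)} | {"hub"}
        pool = enumerate_paths(net, seeds, max_len=4)
        val = stability(pool, seeds, 1.0, k=10, resamples=5, fraction=1.0,
                        rng=np.random.default_rng(0))
        assert val == pytest.approx(1.0)

    def test_jaccard_definition(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert jaccard(set(), set()) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_too_few_resamples_rejected(self, small_scenario):
        pool = enumerate_paths(_net([("a", "b", "ppi")]), {"a", "b"}, 4)
        with pytest.raises(ValueError):
            stability(pool, {"a", "b"}, 1.0, k=5, resamples=1)


class TestSweepAndFinalize:
    def test_unconnectable_seeds_give_empty_result(self):
        net = _net([("a", "x1", "ppi"), ("x1", "x2", "ppi"),
                    ("x2", "x3", "ppi"), ("x3", "x4", "ppi"),
                    ("x4", "b", "ppi")])  # a-b distance 5 > path_length 4
        cfg = PipelineConfig(stability_resamples=3)
        res = sweep_and_finalize(net, {"a", "b"}, cfg)
        assert res.subnetworks == []
        assert not res.per_penalty["accepted"].any()

    def test_single_planted_module_recovered_as_one_component(self):
        from suppnet.simulate import generate_expression, generate_network
        from suppnet.pipeline import run_subnetworks

        matrix, truth = generate_expression(
            n_genes=400, labels_spec={"A": 12, "coreA": 6},
            modules_spec=[12], rng_seed=21)
        net, truth = generate_network(truth, n_background_nodes=40,
                                      rng_seed=22)
        from suppnet.de import de_table
        cfg = PipelineConfig(rng_seed=3)
        de = de_table(matrix, cfg)
        seeds = truth.planted_modules[0]
        sweep, _, _ = run_subnetworks(net, de, set(seeds), cfg)
        assert len(sweep.subnetworks) == 1
        comp = sweep.subnetworks[0]
        assert len(comp.connected_seeds & seeds) >= 0.9 * len(seeds)

    def test_edge_count_monotone_in_penalty(self):
        """Raising the penalty never grows the selected subnetwork.

        Chain of seeds joined by two-edge paths of graded weight: the
        costlier links drop out one by one as the per-edge penalty rises.
        """
        edges, weights = [], {}
        for i, omw in enumerate([0.02, 0.2, 0.45, 0.9]):
            for (a, b) in [(f"s{i}", f"b{i}"), (f"b{i}", f"s{i + 1}")]:
                edges.append((a, b, "ppi"))
                key = (min(a, b), max(a, b), "ppi")
                weights[key] = 1.0 - omw
        net = _net(edges, weights=weights)
        seeds = {f"s{i}" for i in range(5)}
        cfg = PipelineConfig(stability_resamples=3, jaccard_min=0.0)
        res = sweep_and_finalize(net, seeds, cfg)
        n_edges = res.per_penalty["n_edges"].to_numpy()
        assert n_edges[0] > n_edges[-1]
        assert (np.diff(n_edges) <= 0).all()

    def test_connectors_are_never_leaves(self, small_scenario, small_de,
                                         small_config):
        """Score-0 nodes in final components lie between seeds, not at tips."""
        from suppnet.pipeline import run_subnetworks

        _, net, truth = small_scenario
        seeds = set().union(*truth.planted_modules)
        sweep, scores, _ = run_subnetworks(net.copy(), small_de, seeds,
                                           small_config)
        scored = scores["score"].to_dict()
        for sub in sweep.subnetworks:
            degree = {}
            for (u, v, _t) in sub.edges:
                degree[u] = degree.get(u, 0) + 1
                degree[v] = degree.get(v, 0) + 1
            for node in sub.nodes:
                if scored.get(node, 0.0) == 0.0:
                    assert degree.get(node, 0) >= 2


class TestRecoverPlanted:
    def _truth(self):
        truth = SyntheticTruth()
        truth.planted_modules = [{"a", "b", "c", "d"}]
        truth.module_connectors = [set()]
        truth.module_edges = [{("a", "b", "ppi"), ("b", "c", "ppi"),
                               ("c", "d", "ppi")}]
        return truth

    def test_perfect_recovery(self):
        truth = self._truth()
        sub = Subnetwork(edges=set(truth.module_edges[0]),
                         nodes={"a", "b", "c", "d"})
        res = recover_planted([sub], truth)
        assert res.loc[0, ["node_precision", "node_recall", "node_f1"]] \
            .tolist() == [1.0, 1.0, 1.0]

    def test_empty_result_zero_recall(self):
        res = recover_planted([], self._truth())
        assert res.loc[0, "node_recall"] == 0.0

    def test_half_recovered(self):
        sub = Subnetwork(edges={("a", "b", "ppi")}, nodes={"a", "b"})
        res = recover_planted([sub], self._truth())
        assert res.loc[0, "node_precision"] == 1.0
        assert res.loc[0, "node_recall"] == 0.5
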