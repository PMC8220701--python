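"""Shared fixtures: a small planted scenario and brute-force path oracles."""

from __future__ import annotations

import pytest

from suppnet import PipelineConfig
from suppnet.de import de_table
from suppnet.scoring import COST_EPS
from suppnet.simulate import generate_expression, generate_network

SMALL_LABELS = {"A": 8, "coreA": 3, "B": 8, "coreB": 3, "C": 8, "coreC": 2,
                "D": 10, "E": 8, "F": 6}


@pytest.fixture(scope="session")
def small_scenario():
    """600-gene scenario with two planted modules (12 genes each)."""
    matrix, truth = generate_expression(
        n_genes=600, labels_spec=SMALL_LABELS, modules_spec=[12, 12],
        rng_seed=11,
    )
    net, truth = generate_network(truth, n_background_nodes=60, rng_seed=12)
    return matrix, net, truth


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(rng_seed=7)


@pytest.fixture(scope="session")
def small_de(small_scenario, small_config):
    matrix, _net, _truth = small_scenario
    return de_table(matrix, small_config)


def brute_force_paths(net, seed, targets, max_len, penalty_c):
    """Independent enumeration of all bounded simple paths to each target.

    Walks the stored arc structure recursively and prices every edge as
    penalty * (1 - weight) + eps; returns per target the full list sorted
    by (cost, n_edges, node sequence).
    """
    graph = net.graph
    out = {t: [] for t in targets}

    def rec(node, nodes, cost):
        for succ in graph.successors(node):
            if succ in nodes:
                continue
            w = graph[node][succ].get("weight", 0.0)
            c2 = cost + penalty_c * (1.0 - w) + COST_EPS
            n2 = nodes + (succ,)
            if succ in targets and succ != seed:
                out[succ].append((c2, len(n2) - 1, n2))
            if len(n2) - 1 < max_len:
                rec(succ, n2, c2)

    if graph.has_node(seed):
        rec(seed, (seed,), 0.0)
    return {t: sorted(v) for t, v in out.items() if v}


def random_weighted_network(rng, n_nodes=7, n_edges=10):
    """Small random typed network with random edge weights attached."""
    from suppnet.data import WeightedNetwork

    names = [f"N{i}" for i in range(n_nodes)]
    net = WeightedNetwork()
    types = ["regulatory", "ppi", "metabolic"]
    for _ in range(n_edges):
        u, v = rng.choice(names, size=2, replace=False)
        net.add_edge(str(u), str(v), types[int(rng.integers(3))])
    if net.n_edges == 0:
        net.add_edge(names[0], names[1], "ppi")
    weights = {e: float(rng.random()) for e in net.edges()}
    net.set_weights(weights)
    return net
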