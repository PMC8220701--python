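"""Synthetic expression matrices and interaction networks with planted truth.

The generator emulates the shape of a five-genotype microarray study — a
wild-type reference, a primary mutant and three suppressor lines, three
replicates each — at desk scale (5,000 genes, ~20,000 interactions; about
a quarter of an ATH1-class experiment).  Every planted feature is recorded
in a :class:`~suppnet.data.SyntheticTruth` so downstream stages can be
scored against ground truth:

* per-gene log2 baselines ~ Normal(8, 1.5), per-gene noise variances drawn
  from a scaled inverse chi-square (inverse-gamma) so variance moderation
  has something to moderate;
* differential-expression effects planted so each gene's label under ideal
  thresholding equals its restored/compensatory/non-restored group;
* an interaction network from degree-biased random attachment, with
  planted modules wired as hub-and-spoke subgraphs (diameter <= 4 edges)
  over module seeds, optionally routed through a few non-DE connector
  nodes.
"""

from __future__ import annotations

import functools
import json
import logging
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data import ExpressionMatrix, SyntheticTruth, WeightedNetwork, canonical_edge

log = logging.getLogger(__name__)

DEFAULT_LINES = ("WS2", "bri1-5", "brs1-1D", "bri1-1D", "bak1-1D")

#: Desk-scale group sizes: the published group sizes (270/178/371 with
#: cores 118/23/149, plus 333/167/94 line-specific genes) scaled by
#: 5,000 / 22,810 genes and rounded.
DEFAULT_LABELS_SPEC = {
    "A": 59, "coreA": 26,
    "B": 39, "coreB": 5,
    "C": 81, "coreC": 33,
    "D": 73, "E": 37, "F": 21,
}

#: Edge-type mix of the compiled-network shape (regulatory : ppi : metabolic).
EDGE_TYPE_PROPS = {"regulatory": 0.33, "ppi": 0.50, "metabolic": 0.17}

# DE-flag patterns (mutant, s1, s2, s3) realizing each label.  Non-core
# variants cycle through the listed alternatives.
_CORE_PATTERNS = {
    "A": (True, (False, False, False)),
    "B": (False, (True, True, True)),
    "C": (True, (True, True, True)),
}
_NONCORE_PATTERNS = {
    "A": [(True, (True, False, False)), (True, (False, True, False)),
          (True, (False, False, True))],
    "B": [(False, (True, True, False)), (False, (True, False, True)),
          (False, (False, True, True))],
    "C": [(True, (True, True, False)), (True, (True, False, True)),
          (True, (False, True, True))],
}
_SINGLE_PATTERNS = {
    "D": (False, (True, False, False)),
    "E": (False, (False, True, False)),
    "F": (False, (False, False, True)),
}


@functools.lru_cache(maxsize=None)
def _maxabs_contrast_kappa(n_contrasts: int = 4, n_replicates: int = 3,
                           mc: int = 200_000) -> float:
    """E[(max-|logFC| of a null gene)^2] / s_g^2, computed numerically.

    The four contrasts share the reference-line mean, so their logFC
    estimates are equicorrelated Normals; the constant is evaluated once
    by fixed-seed Monte Carlo (it depends only on the design, not on the
    simulation seed).
    """
    rng = np.random.default_rng(987_654_321)
    line_means = rng.standard_normal((mc, n_contrasts)) / math.sqrt(n_replicates)
    ref_mean = rng.standard_normal((mc, 1)) / math.sqrt(n_replicates)
    m = np.abs(line_means - ref_mean).max(axis=1)
    return float(np.mean(m ** 2))


def generate_expression(
    n_genes: int = 5000,
    n_replicates: int = 3,
    labels_spec: dict[str, int] | None = None,
    effect_range: tuple[float, float] = (1.0, 3.0),
    noise_spec: tuple[float, float] = (6.0, 0.03),
    rng_seed: int = 0,
    lines: tuple[str, ...] = DEFAULT_LINES,
    fc_threshold: float = 1.5,
    modules_spec: list[int] | None = None,
    baseline: tuple[float, float] = (8.0, 1.5),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate log2 intensities with planted group structure.

    ``labels_spec`` gives target counts per group label ("A".."F", with
    "coreX" counting the unanimous subset of X).  ``effect_range`` is the
    planted |log2 effect| interval; its lower end must exceed
    log2(fc_threshold) or the planted truth would be undetectable even
    with ideal power.  ``noise_spec`` = (d0, s0^2) of the scaled inverse
    chi-square the per-gene noise variances are drawn from.
    ``modules_spec`` lists planted-module sizes; members are drawn from
    the genes labelled A/B/C (the seed groups).
    """
    labels_spec = dict(DEFAULT_LABELS_SPEC if labels_spec is None else labels_spec)
    lo, hi = effect_range
    if lo <= math.log2(fc_threshold):
        raise ValueError(
            f"effect_range lower bound {lo} must exceed log2(fc_threshold) "
            f"= {math.log2(fc_threshold):.4f}: planted truth would be undetectable"
        )
    if len(lines) < 2:
        raise ValueError("need a reference line and at least one mutant line")
    d0, s0_sq = noise_spec
    if d0 <= 2:
        raise ValueError("noise_spec prior df must exceed 2 (finite mean variance)")
    rng = np.random.default_rng(rng_seed)
    reference, mutant, *suppressors = lines
    if len(suppressors) != 3:
        raise ValueError("the planted group logic needs exactly 3 suppressor lines")

    genes = [f"AT{(i % 5) + 1}G{i:05d}" for i in range(n_genes)]
    # assign labels to a random subset of genes
    wanted: list[tuple[str, bool]] = []
    for label in ("A", "B", "C"):
        n_total = labels_spec.get(label, 0)
        n_core = labels_spec.get("core" + label, 0)
        if n_core > n_total:
            raise ValueError(f"core{label} count exceeds {label} count")
        wanted += [(label, True)] * n_core + [(label, False)] * (n_total - n_core)
    for label in ("D", "E", "F"):
        wanted += [(label, False)] * labels_spec.get(label, 0)
    if len(wanted) > n_genes:
        raise ValueError("labels_spec asks for more labelled genes than n_genes")
    chosen = rng.choice(n_genes, size=len(wanted), replace=False)

    truth = SyntheticTruth()
    truth.group_of = {g: ("none", False) for g in genes}
    effects = np.zeros((n_genes, len(lines)))
    noncore_cycle = {label: 0 for label in ("A", "B", "C")}
    for (label, core), gi in zip(wanted, chosen):
        gene = genes[gi]
        truth.group_of[gene] = (label, core)
        if label in ("A", "B", "C"):
            if core:
                mut_de, sup_de = _CORE_PATTERNS[label]
            else:
                alts = _NONCORE_PATTERNS[label]
                mut_de, sup_de = alts[noncore_cycle[label] % len(alts)]
                noncore_cycle[label] += 1
        else:
            mut_de, sup_de = _SINGLE_PATTERNS[label]
        sign = 1.0 if rng.random() < 0.5 else -1.0  # up/down in equal proportion
        flags = (mut_de, *sup_de)
        for j, flag in enumerate(flags, start=1):  # column 0 is the reference
            if flag:
                effects[gi, j] = sign * rng.uniform(lo, hi)
                truth.effect_of[(gene, lines[j])] = effects[gi, j]

    baselines = rng.normal(baseline[0], baseline[1], size=n_genes)
    # s_g^2 ~ scaled-inv-chi2(d0, s0^2) = InvGamma(d0/2, d0*s0^2/2)
    s2 = (d0 * s0_sq / 2.0) / rng.gamma(d0 / 2.0, 1.0, size=n_genes)
    sd = np.sqrt(s2)

    columns, data = [], []
    for j, line in enumerate(lines):
        for r in range(1, n_replicates + 1):
            columns.append(f"{line}_r{r}")
            data.append(
                baselines + effects[:, j] + rng.normal(0.0, 1.0, n_genes) * sd
            )
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    samples = pd.DataFrame(
        {
            "line": [c.rsplit("_r", 1)[0] for c in columns],
            "replicate": [int(c.rsplit("_r", 1)[1]) for c in columns],
        },
        index=pd.Index(columns, name="sample"),
    )

    kappa = _maxabs_contrast_kappa(len(lines) - 1, n_replicates)
    mean_s2 = d0 * s0_sq / (d0 - 2.0)
    truth.null_params = (0.0, math.sqrt(kappa * mean_s2))

    if modules_spec:
        pool = sorted(
            g for g, (lab, _) in truth.group_of.items() if lab in ("A", "B", "C")
        )
        if sum(modules_spec) > len(pool):
            raise ValueError(
                f"modules_spec needs {sum(modules_spec)} A/B/C genes, "
                f"only {len(pool)} planted"
            )
        shuffled = list(rng.permutation(pool))
        start = 0
        for size in modules_spec:
            truth.planted_modules.append(set(shuffled[start:start + size]))
            start += size

    log.info("generated %d genes x %d samples; %d labelled genes, %d modules",
             n_genes, len(columns), len(wanted), len(truth.planted_modules))
    return ExpressionMatrix(values=values, samples=samples), truth


def generate_network(
    truth: SyntheticTruth,
    n_background_nodes: int = 200,
    background_degree: int = 8,
    module_internal_weight_bias: float = 0.25,
    rng_seed: int = 0,
    path_length: int = 4,
    edge_type_props: dict[str, float] | None = None,
) -> tuple[WeightedNetwork, SyntheticTruth]:
    """Background interaction graph plus wired planted modules.

    The background is a degree-biased random-attachment (preferential
    attachment) graph over all expression genes plus ``n_background_nodes``
    extra connector genes, with mean degree ~``background_degree`` and
    edge types at the stated proportions (directed types oriented at
    random).  Each planted module becomes a hub-and-spoke subgraph over
    its seeds: spokes are undirected ppi edges, a fraction are routed
    through 0-2 non-DE connector nodes, and each member gains an extra
    random intra-module edge with probability
    ``module_internal_weight_bias`` — all internal paths stay within
    ``path_length`` edges.
    """
    if path_length < 2:
        raise ValueError("path_length must be >= 2 to wire a module")
    props = dict(EDGE_TYPE_PROPS if edge_type_props is None else edge_type_props)
    rng = np.random.default_rng(rng_seed)
    genes = sorted(truth.group_of)
    connectors = [f"CONN{i:04d}" for i in range(n_background_nodes)]
    all_nodes = genes + connectors
    n = len(all_nodes)
    m = max(1, round(background_degree / 2))
    ba = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2 ** 31)))
    order = rng.permutation(n)
    name_of = {i: all_nodes[order[i]] for i in range(n)}
    module_id = {
        g: i for i, module in enumerate(truth.planted_modules) for g in module
    }

    net = WeightedNetwork()
    types = list(props)
    probs = np.array([props[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    for u, v in ba.edges():
        a, b = name_of[u], name_of[v]
        # keep planted structure identifiable: a member's interactions are
        # exclusively its module wiring; modules touch the background only
        # through their connector genes
        if a in module_id or b in module_id:
            continue
        etype = types[rng.choice(len(types), p=probs)]
        if etype != "ppi" and rng.random() < 0.5:
            a, b = b, a
        net.add_edge(a, b, etype)

    truth.module_connectors = []
    truth.module_edges = []
    conn_iter = iter(connectors)
    for module in truth.planted_modules:
        members = sorted(module)
        # hub = the member with the strongest planted effect (ties: name)
        strength = {
            g: max(
                (abs(e) for (gg, _l), e in truth.effect_of.items() if gg == g),
                default=0.0,
            )
            for g in members
        }
        hub = max(members, key=lambda g: (strength[g], g))
        n_conn = int(rng.integers(0, 3)) if path_length >= 4 else 0
        used_conns = [next(conn_iter) for _ in range(n_conn)]
        module_edge_keys: set[tuple[str, str, str]] = set()

        def _wire(a: str, b: str, etype: str = "ppi") -> None:
            net.add_edge(a, b, etype)
            module_edge_keys.add(canonical_edge(a, b, etype))

        for node in members:
            if node == hub:
                continue
            _wire(node, hub)  # direct spoke: internal paths <= 2 edges
            # redundant regulator fan-out from the hub (central-regulator motif)
            if rng.random() < module_internal_weight_bias:
                _wire(hub, node, "regulatory")
        for conn in used_conns:
            # connector shortcut paths member - connector - hub
            _wire(conn, hub)
            for node in rng.choice(members, size=min(2, len(members)),
                                    replace=False):
                if node != hub:
                    _wire(str(node), conn)
        truth.module_connectors.append(set(used_conns))
        truth.module_edges.append(module_edge_keys)
        _check_module_diameter(module_edge_keys, members, used_conns, path_length)

    log.info("generated network: %d nodes, %d edges, %d planted modules",
             net.n_nodes, net.n_edges, len(truth.planted_modules))
    return net, truth


def _check_module_diameter(edges, members, conns, path_length) -> None:
    g = nx.Graph()
    g.add_nodes_from(members)
    g.add_nodes_from(conns)
    for (u, v, _t) in edges:
        g.add_edge(u, v)
    if not nx.is_connected(g):
        raise ValueError("planted module wiring is not connected")
    diam = nx.diameter(g)
    if diam > path_length:
        raise ValueError(
            f"planted module not reachable within path_length: diameter {diam}"
        )


def default_scenario(rng_seed: int = 1) -> tuple[
    ExpressionMatrix, WeightedNetwork, SyntheticTruth
]:
    """The standard planted-recovery benchmark.

    5,000 genes x 5 lines x 3 replicates, three planted modules of
    18/20/22 genes whose members make up groups A/B/C (20 genes each, 8
    core), the usual line-specific groups, and a ~20,000-edge background
    network.
    """
    labels = {"A": 20, "coreA": 8, "B": 20, "coreB": 8, "C": 20, "coreC": 8,
              "D": 73, "E": 37, "F": 21}
    matrix, truth = generate_expression(
        n_genes=5000, labels_spec=labels, modules_spec=[18, 20, 22],
        rng_seed=rng_seed,
    )
    net, truth = generate_network(truth, rng_seed=rng_seed + 1)
    return matrix, net, truth


def generate_feedback_scenario(
    n_genes: int = 400,
    n_pathway_genes: int = 5,
    magnitudes: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5),
    noise_sd: float = 0.1,
    rng_seed: int = 0,
    lines: tuple[str, ...] = DEFAULT_LINES,
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Expression matrix with a planted monotone feedback trend.

    A small gene set (e.g. hormone-biosynthesis genes) is perturbed in
    every non-reference line with |effect| increasing along the returned
    best-to-worst line ranking — emulating weaker feedback deregulation in
    lines that suppress the phenotype better.  Returns (matrix, pathway
    genes, ranking best->worst).
    """
    rng = np.random.default_rng(rng_seed)
    reference, *rest = lines
    if len(magnitudes) != len(rest):
        raise ValueError("need one magnitude per non-reference line")
    # best-suppressing line = smallest |effect|; ranking best -> worst
    ranking = [line for _, line in sorted(zip(magnitudes, rest))]
    genes = [f"AT{(i % 5) + 1}G{i:05d}" for i in range(n_genes)]
    pathway = genes[:n_pathway_genes]
    baselines = rng.normal(8.0, 1.0, size=n_genes)
    columns, data = [], []
    for j, line in enumerate(lines):
        effect = np.zeros(n_genes)
        if j > 0:
            effect[:n_pathway_genes] = -magnitudes[j - 1]  # down-regulated
        for r in range(1, 4):
            columns.append(f"{line}_r{r}")
            data.append(baselines + effect + rng.normal(0, noise_sd, n_genes))
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    samples = pd.DataFrame(
        {
            "line": [c.rsplit("_r", 1)[0] for c in columns],
            "replicate": [int(c.rsplit("_r", 1)[1]) for c in columns],
        },
        index=pd.Index(columns, name="sample"),
    )
    return ExpressionMatrix(values=values, samples=samples), pathway, ranking


# ---------------------------------------------------------------------------
# truth (de)serialization for the CLI
# ---------------------------------------------------------------------------

def truth_to_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "group_of": {g: [lab, core] for g, (lab, core) in truth.group_of.items()},
        "effect_of": [[g, line, e] for (g, line), e in truth.effect_of.items()],
        "planted_modules": [sorted(m) for m in truth.planted_modules],
        "module_connectors": [sorted(c) for c in truth.module_connectors],
        "module_edges": [sorted(list(e) for e in edges)
                         for edges in truth.module_edges],
        "null_params": list(truth.null_params),
    }
    Path(path).write_text(json.dumps(payload))


def truth_from_json(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    truth = SyntheticTruth()
    truth.group_of = {g: (lab, bool(core))
                      for g, (lab, core) in payload["group_of"].items()}
    truth.effect_of = {(g, line): float(e) for g, line, e in payload["effect_of"]}
    truth.planted_modules = [set(m) for m in payload["planted_modules"]]
    truth.module_connectors = [set(c) for c in payload["module_connectors"]]
    truth.module_edges = [
        {tuple(e) for e in edges} for edges in payload["module_edges"]
    ]
    truth.null_params = tuple(payload["null_params"])
    return truth
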