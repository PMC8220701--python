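"""Core in-memory containers shared by every pipeline stage.

The pipeline compares a loss-of-function mutant line against its wild-type
reference and a set of activation-tag suppressor lines on a gene-level log2
expression matrix, then connects the differentially expressed genes on a
typed molecular interaction network.  The containers here are deliberately
thin wrappers over pandas / networkx objects so each stage can use the
ecosystem's native operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

#: Allowed interaction types.  Regulatory and metabolic edges are directed
#: (regulator -> regulated, substrate -> product); protein-protein (ppi)
#: edges are undirected.
EDGE_TYPES = ("regulatory", "ppi", "metabolic")
DIRECTED_TYPES = frozenset({"regulatory", "metabolic"})


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 intensities plus sample -> (line, replicate) metadata.

    ``values`` is indexed by gene (or probe, upstream of probe collapsing)
    with one column per sample.  ``samples`` is indexed by sample ID with
    columns ``line`` and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(
                f"samples missing from metadata: {', '.join(map(str, missing))}"
            )
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for line in self.samples["line"]:
            seen.setdefault(line, None)
        return list(seen)

    def samples_of(self, line: str) -> list[str]:
        sel = self.samples.index[self.samples["line"] == line]
        if len(sel) == 0:
            raise KeyError(f"no samples for line {line!r}")
        return list(sel)

    def line_values(self, line: str) -> pd.DataFrame:
        return self.values[self.samples_of(line)]

    def line_means(self) -> pd.DataFrame:
        """Per-line mean of replicates (gene x line)."""
        return pd.DataFrame(
            {line: self.line_values(line).mean(axis=1) for line in self.lines}
        )


def canonical_edge(u: str, v: str, etype: str) -> tuple[str, str, str]:
    """Direction-blind edge identity used for Jaccard / size accounting."""
    a, b = (u, v) if u <= v else (v, u)
    return (a, b, etype)


class WeightedNetwork:
    """Typed, partially directed interaction graph.

    Internally a :class:`networkx.DiGraph`; undirected ppi edges are stored
    as arc pairs so that path search can treat direction uniformly.  Each
    arc carries ``etype`` and optionally ``weight`` (relevance in [0, 1]).
    Edge *identity* (for deduplication, Jaccard indices and size bounds) is
    always the direction-blind ``(min(u,v), max(u,v), etype)`` triple.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self._edges: set[tuple[str, str, str]] = set()

    def add_edge(self, source: str, target: str, etype: str) -> bool:
        """Add one interaction; returns False for duplicates/self-loops."""
        if etype not in EDGE_TYPES:
            raise ValueError(
                f"unknown edge type {etype!r}; allowed: {', '.join(EDGE_TYPES)}"
            )
        if source == target:
            return False
        if etype in DIRECTED_TYPES:
            key = (source, target, etype)
        else:
            key = canonical_edge(source, target, etype)
        if key in self._edges:
            return False
        self._edges.add(key)
        self.graph.add_edge(source, target, etype=etype)
        if etype not in DIRECTED_TYPES:
            self.graph.add_edge(target, source, etype=etype)
        return True

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Unique interactions (arc pairs of a ppi edge count once)."""
        return len(self._edges)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, str]]:
        """Stored edges as (source, target, etype), ppi in canonical order."""
        return sorted(self._edges)

    def has_node(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def set_weights(self, weight_of: dict[tuple[str, str, str], float]) -> None:
        """Attach relevance weights keyed by the stored-edge triple."""
        for (u, v, etype) in self._edges:
            w = weight_of[(u, v, etype)]
            self.graph[u][v]["weight"] = w
            if etype not in DIRECTED_TYPES:
                self.graph[v][u]["weight"] = w

    def copy(self) -> "WeightedNetwork":
        out = WeightedNetwork()
        out.graph = self.graph.copy()
        out._edges = set(self._edges)
        return out


@dataclass
class Subnetwork:
    """One inferred subnetwork: selected edges plus bookkeeping.

    ``edges`` holds direction-blind (u, v, etype) triples; ``connected_seeds``
    the seed genes joined by selected paths; ``selection_score`` the
    coverage-minus-cost objective value; ``stability`` the mean pairwise
    Jaccard over seed resamples at this penalty (NaN when not computed).
    """

    edges: set[tuple[str, str, str]] = field(default_factory=set)
    nodes: set[str] = field(default_factory=set)
    connected_seeds: set[str] = field(default_factory=set)
    selection_score: float = 0.0
    penalty_c: float = float("nan")
    stability: float = float("nan")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def connector_genes(self, seeds: set[str]) -> set[str]:
        """Nodes recovered without being seeds (not DE themselves)."""
        return self.nodes - set(seeds)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic generator.

    group_of maps gene -> (label, core); effect_of maps (gene, line) ->
    planted log2 effect; planted_modules lists gene sets wired to be
    recoverable as subnetworks; null_params is the (mu, sigma) the
    background max-logFC distribution is built to follow.
    """

    group_of: dict[str, tuple[str, bool]] = field(default_factory=dict)
    effect_of: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_modules: list[set[str]] = field(default_factory=list)
    module_connectors: list[set[str]] = field(default_factory=list)
    module_edges: list[set[tuple[str, str, str]]] = field(default_factory=list)
    null_params: tuple[float, float] = (0.0, 0.0)

    def genes_with_label(self, label: str, core: bool | None = None) -> set[str]:
        return {
            g
            for g, (lab, is_core) in self.group_of.items()
            if lab == label and (core is None or is_core == core)
        }
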