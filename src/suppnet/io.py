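"""Readers and writers for the pipeline's external formats.

Formats are all plain text: expression TSV (genes x samples) with a sample
metadata TSV, typed edge-list TSV, GMT gene-set collections, two-column GO
annotation TSV, marker-gene tables, and node/edge/GraphML output for
inferred subnetworks.  Gene identifiers are opaque case-sensitive strings.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .data import EDGE_TYPES, ExpressionMatrix, Subnetwork, WeightedNetwork

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, metadata: str | Path) -> ExpressionMatrix:
    """Load a gene x sample log2 matrix plus sample -> (line, replicate) map.

    The matrix TSV has a header row of sample IDs and gene/probe IDs in the
    first column; the metadata TSV has columns ``sample``, ``line``,
    ``replicate``.  Every matrix sample must appear in the metadata.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata, sep="\t", dtype={"sample": str})
    for col in ("sample", "line", "replicate"):
        if col not in meta.columns:
            raise ValueError(f"metadata {metadata} lacks column {col!r}")
    meta = meta.set_index("sample")
    matrix = ExpressionMatrix(values=values, samples=meta)
    log.info(
        "read expression: %d genes x %d samples, %d lines",
        values.shape[0], values.shape[1], len(matrix.lines),
    )
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     metadata: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    matrix.samples.to_csv(metadata, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------

def read_network(path: str | Path) -> WeightedNetwork:
    """Load a typed edge list (columns source, target, type).

    Regulatory and metabolic rows become directed edges, ppi rows
    undirected; duplicate rows and self-loops are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source", "target", "type"):
        if col not in df.columns:
            raise ValueError(f"edge list {path} lacks column {col!r}")
    bad = sorted(set(df["type"]) - set(EDGE_TYPES))
    if bad:
        raise ValueError(
            f"unknown edge type(s) {', '.join(bad)}; allowed: "
            + ", ".join(EDGE_TYPES)
        )
    net = WeightedNetwork()
    for row in df.itertuples(index=False):
        net.add_edge(row.source, row.target, row.type)
    log.info("read network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    rows = [{"source": u, "target": v, "type": t} for u, v, t in net.edges()]
    pd.DataFrame(rows, columns=["source", "target", "type"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets and annotations
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: name <TAB> description <TAB> member...; members deduplicated."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        sets[name] = {m for m in parts[2:] if m}
    return sets


def write_gene_sets(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, ""] + sorted(set(members)))
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Two-column gene <TAB> term TSV -> term -> gene-set mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.term, set()).add(row.gene)
    return out


def read_markers(path: str | Path, min_references: int = 5) -> pd.DataFrame:
    """Marker-gene table (gene, direction in {up, down}, n_references).

    Markers below ``min_references`` independent literature reports are
    dropped (the inclusion rule for high-confidence hormone-response
    markers); unknown directions raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "direction": str})
    for col in ("gene", "direction", "n_references"):
        if col not in df.columns:
            raise ValueError(f"marker table {path} lacks column {col!r}")
    bad = sorted(set(df["direction"]) - {"up", "down"})
    if bad:
        raise ValueError(f"unknown marker direction(s): {', '.join(bad)}")
    kept = df[df["n_references"] >= min_references].reset_index(drop=True)
    log.info("read markers: %d of %d with >= %d references",
             len(kept), len(df), min_references)
    return kept


# ---------------------------------------------------------------------------
# subnetwork output
# ---------------------------------------------------------------------------

def write_subnetworks(
    subnetworks: list[Subnetwork],
    prefix: str | Path,
    seeds: set[str] | None = None,
    group_of: dict[str, tuple[str, bool]] | None = None,
    gene_scores: dict[str, float] | None = None,
    edge_weights: dict[tuple[str, str, str], float] | None = None,
) -> dict[str, Path]:
    """Emit node TSV, edge TSV and GraphML for a list of subnetworks.

    Node table columns: subnetwork, gene, group, core, connector, gene_score.
    Edge table columns: subnetwork, source, target, type, weight.  The
    GraphML file carries the same attributes for generic viewers.
    """
    prefix = Path(prefix)
    seeds = seeds or set()
    group_of = group_of or {}
    gene_scores = gene_scores or {}
    edge_weights = edge_weights or {}

    node_rows, edge_rows = [], []
    gml = nx.Graph()
    for i, sub in enumerate(subnetworks, start=1):
        for gene in sorted(sub.nodes):
            label, core = group_of.get(gene, ("none", False))
            connector = gene not in seeds
            node_rows.append({
                "subnetwork": i, "gene": gene, "group": label,
                "core": core, "connector": connector,
                "gene_score": gene_scores.get(gene, float("nan")),
            })
            gml.add_node(gene, subnetwork=i, group=label, core=bool(core),
                         connector=bool(connector),
                         gene_score=float(gene_scores.get(gene, float("nan"))))
        for (u, v, etype) in sorted(sub.edges):
            w = edge_weights.get((u, v, etype), float("nan"))
            edge_rows.append({
                "subnetwork": i, "source": u, "target": v,
                "type": etype, "weight": w,
            })
            gml.add_edge(u, v, etype=etype, weight=float(w))

    node_path = prefix.with_name(prefix.name + "_nodes.tsv")
    edge_path = prefix.with_name(prefix.name + "_edges.tsv")
    gml_path = prefix.with_name(prefix.name + ".graphml")
    pd.DataFrame(
        node_rows,
        columns=["subnetwork", "gene", "group", "core", "connector", "gene_score"],
    ).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(
        edge_rows, columns=["subnetwork", "source", "target", "type", "weight"]
    ).to_csv(edge_path, sep="\t", index=False)
    nx.write_graphml(gml, gml_path)
    log.info("wrote %d subnetworks to %s{_nodes.tsv,_edges.tsv,.graphml}",
             len(subnetworks), prefix)
    return {"nodes": node_path, "edges": edge_path, "graphml": gml_path}


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "line": str})
    df["de_flag"] = df["de_flag"].astype(bool)
    return df
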