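"""End-to-end orchestration: simulate -> DE -> groups -> score -> subnetworks.

Also houses the reproduction entry points that recompute the published
summary numbers from user-supplied local copies of the study's data
(supplementary gene lists and the deposited expression matrix); see
:func:`reproduce_from_supplementary` and :func:`reproduce_from_accession`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import groups as groups_mod
from . import io as io_mod
from . import scoring, simulate, subnet
from .config import PipelineConfig
from .data import ExpressionMatrix, SyntheticTruth, WeightedNetwork

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    config: PipelineConfig
    de: pd.DataFrame
    assignment: pd.DataFrame
    scores: pd.DataFrame
    null: scoring.NullModel
    sweep: subnet.SweepResult
    seeds: set[str]
    recovery: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def run_de_and_groups(matrix: ExpressionMatrix, config: PipelineConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    de = de_mod.de_table(matrix, config)
    flags = de_mod.de_flag_matrix(de)
    config.require_three_suppressors()
    assignment = groups_mod.classify_groups(
        flags, config.mutant_line, list(config.suppressor_lines)
    )
    return de, assignment


def run_subnetworks(
    net: WeightedNetwork,
    de: pd.DataFrame,
    seeds: set[str],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> tuple[subnet.SweepResult, pd.DataFrame, scoring.NullModel]:
    scores, null = scoring.score_genes(de, list(config.non_reference_lines))
    scoring.weight_network(net, scores)
    rng = rng or np.random.default_rng(config.rng_seed)
    sweep = subnet.sweep_and_finalize(net, seeds, config, rng=rng)
    return sweep, scores, null


def run_synthetic(
    config: PipelineConfig | None = None,
    rng_seed: int = 1,
    seeds_from: str = "planted",
) -> tuple[PipelineResult, SyntheticTruth]:
    """Full pipeline on the standard planted-recovery scenario.

    ``seeds_from``: "planted" uses the planted A/B/C genes as the seed
    list for network inference; "computed" uses the groups called by the
    DE stage (fully end-to-end, but sensitive to DE false positives).
    """
    config = config or PipelineConfig(rng_seed=rng_seed)
    matrix, net, truth = simulate.default_scenario(rng_seed)
    de, assignment = run_de_and_groups(matrix, config)
    if seeds_from == "planted":
        seeds = {
            g for g, (lab, _) in truth.group_of.items() if lab in ("A", "B", "C")
        }
    elif seeds_from == "computed":
        seeds = groups_mod.seed_genes(assignment)
    else:
        raise ValueError("seeds_from must be 'planted' or 'computed'")
    sweep, scores, null = run_subnetworks(net, de, seeds, config)
    recovery = subnet.recover_planted(sweep.subnetworks, truth)
    return (
        PipelineResult(config=config, de=de, assignment=assignment,
                       scores=scores, null=null, sweep=sweep, seeds=seeds,
                       recovery=recovery),
        truth,
    )


def negative_control_f1(
    net: WeightedNetwork,
    de: pd.DataFrame,
    truth: SyntheticTruth,
    config: PipelineConfig,
    n_seeds: int,
    rng: np.random.Generator,
) -> float:
    """Best node F1 over planted modules for a random seed set of equal size.

    Seeds are drawn from expression genes outside the planted modules; a
    sound pipeline should recover (at most) scattered fragments, so the
    matched F1 stays near zero.
    """
    planted = set().union(*truth.planted_modules) if truth.planted_modules else set()
    pool = sorted(set(truth.group_of) - planted)
    seeds = set(rng.choice(pool, size=n_seeds, replace=False))
    sweep, _, _ = run_subnetworks(net.copy(), de, seeds, config, rng=rng)
    recovery = subnet.recover_planted(sweep.subnetworks, truth)
    return float(recovery["node_f1"].max()) if len(recovery) else 0.0


# ---------------------------------------------------------------------------
# reproduction from the study's own data (user-supplied local files)
# ---------------------------------------------------------------------------

def reproduce_from_supplementary(
    gene_table: str | Path,
    marker_table: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Recompute group sizes and marker counts from the study's gene lists.

    ``gene_table``: TSV with columns gene, then one boolean DE-flag column
    per line (mutant and the three suppressors), as exported from the
    study's supplementary gene list.  ``marker_table``: marker TSV (gene,
    direction, n_references) plus a ``de_in_mutant`` boolean column or the
    same flags.  Returns the deterministic set-logic counts.
    """
    config = config or PipelineConfig()
    flags = pd.read_csv(gene_table, sep="\t", index_col=0).astype(bool)
    assignment = groups_mod.classify_groups(
        flags, config.mutant_line, list(config.suppressor_lines)
    )
    sets = groups_mod.group_sets(assignment)
    markers = io_mod.read_markers(marker_table)
    retained = markers[markers["gene"].isin(
        set(flags.index[flags[config.mutant_line]])
    )]
    out = {f"group_{k}": float(len(v)) for k, v in sets.items()}
    out["n_markers"] = float(len(markers))
    out["n_markers_de_in_mutant"] = float(len(retained))
    return out


def reproduce_from_accession(
    expression: str | Path,
    metadata: str | Path,
    probe_map: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Recompute DE counts and the suppressor-similarity R^2 from a local
    copy of the deposited expression matrix.

    ``expression``/``metadata``: the probe- or gene-level log2 matrix and
    sample map; ``probe_map``: optional probe -> gene TSV for collapsing.
    Returns total unique DE genes over the four contrasts and the squared
    correlation of the two most similar suppressors relative to the
    mutant.
    """
    config = config or PipelineConfig()
    matrix = io_mod.read_expression(expression, metadata)
    qn = de_mod.quantile_normalize(matrix.values)
    matrix = ExpressionMatrix(values=qn, samples=matrix.samples)
    if probe_map is not None:
        mapping_df = pd.read_csv(probe_map, sep="\t", dtype=str)
        mapping: dict[str, list[str]] = {}
        for row in mapping_df.itertuples(index=False):
            mapping.setdefault(row[0], []).append(row[1])
        matrix = de_mod.collapse_probes(matrix, mapping)
    de, assignment = run_de_and_groups(matrix, config)
    flags = de_mod.de_flag_matrix(de)
    n_de = int(flags.any(axis=1).sum())
    s1, s2, _ = config.suppressor_lines
    r2 = groups_mod.relative_de_correlation(de, config.mutant_line, s1, s2)
    counts = assignment["label"].value_counts()
    return {
        "n_de_genes": float(n_de),
        "r2_first_two_suppressors": float(r2),
        **{f"group_{k}": float(counts.get(k, 0)) for k in "ABCDEF"},
    }
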