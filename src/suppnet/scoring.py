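"""Empirical-null gene scoring and edge weighting.

Most genes do not respond to the mutations, so the per-gene "largest"
logFC across the contrasted lines is dominated by null genes; a Gaussian
fitted to it by maximum likelihood serves as the empirical null
distribution.  Each gene is then scored two-tailed against that null,

    gene_score = | 1 - 2 * Phi_(mu, sigma)(x) |,

a value in [0, 1] that is 0 at the null mean and approaches 1 far out in
either tail.  Edge relevance is the product of its endpoints' gene scores;
the path-search cost of an edge at penalty c is ``c * (1 - weight) + eps``
with a fixed floor eps = 1e-3 keeping all costs positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import WeightedNetwork
from .de import logfc_matrix

log = logging.getLogger(__name__)

#: Cost floor keeping every edge cost positive (no zero-cost cycles).
COST_EPS = 1e-3


@dataclass(frozen=True)
class NullModel:
    """Gaussian empirical null of the selected per-gene logFC."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


def select_max_logfc(de: pd.DataFrame, lines: list[str] | None = None) -> pd.Series:
    """Per gene, the logFC of largest absolute value across lines, sign kept.

    Ties in absolute value resolve to the first line in column order.
    """
    logfc = logfc_matrix(de)
    if lines is not None:
        logfc = logfc[list(lines)]
    arr = logfc.to_numpy(dtype=float)
    idx = np.argmax(np.abs(arr), axis=1)
    return pd.Series(arr[np.arange(len(arr)), idx], index=logfc.index, name="x")


def fit_null(x) -> NullModel:
    """Gaussian maximum-likelihood fit: sample mean, s.d. with 1/n denominator."""
    x = np.asarray(x, dtype=float)
    if len(x) < 30:
        raise ValueError("need at least 30 values to fit the null")
    sigma = float(np.std(x))  # ddof=0: the MLE
    if sigma == 0:
        raise ValueError("null fit degenerate: zero variance")
    return NullModel(mu=float(np.mean(x)), sigma=sigma)


def gene_score(x, null: NullModel):
    """Two-tailed score |1 - 2 Phi((x - mu)/sigma)| in [0, 1]."""
    z = (np.asarray(x, dtype=float) - null.mu) / null.sigma
    score = np.abs(1.0 - 2.0 * stats.norm.cdf(z))
    return float(score) if score.ndim == 0 else score


def edge_weight(source_score: float, target_score: float) -> float:
    """Relevance of an edge: product of its endpoint gene scores."""
    return source_score * target_score


def edge_cost(weight: float, penalty_c: float) -> float:
    """Traversal cost at penalty c: c * (1 - weight) + eps, always positive."""
    return penalty_c * (1.0 - weight) + COST_EPS


def score_genes(de: pd.DataFrame, lines: list[str] | None = None
                ) -> tuple[pd.DataFrame, NullModel]:
    """Select per-gene logFC, fit the null and score every gene.

    Returns (frame with columns x, score indexed by gene, fitted null).
    """
    x = select_max_logfc(de, lines)
    null = fit_null(x.to_numpy())
    scores = pd.DataFrame({"x": x, "score": gene_score(x.to_numpy(), null)})
    log.info("fitted null mu=%.4f sigma=%.4f over %d genes",
             null.mu, null.sigma, len(x))
    return scores, null


def weight_network(net: WeightedNetwork, scores: pd.DataFrame
                   ) -> dict[tuple[str, str, str], float]:
    """Attach product weights to every edge; genes without scores get 0.

    Score-0 genes make incident edges maximally expensive yet traversable,
    so non-DE genes can still be picked up as connectors on short paths.
    """
    score_of = scores["score"].to_dict()
    weights = {
        (u, v, t): edge_weight(score_of.get(u, 0.0), score_of.get(v, 0.0))
        for (u, v, t) in net.edges()
    }
    net.set_weights(weights)
    return weights
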