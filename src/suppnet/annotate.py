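"""Enrichment and summary statistics for gene groups and subnetworks.

Over-representation uses the hypergeometric upper tail: drawing ``n``
query genes from a universe of ``N`` of which ``K`` carry a term, the
enrichment p-value is P(X >= k) for the observed overlap k, BH-adjusted
across terms.  Per-line comparisons use one-way ANOVA with Tukey HSD
pairwise tests summarized as a compact letter display ("a" = highest
mean; lines sharing a letter are not significantly different).  The
feedback-trend statistic asks whether a pathway's deregulation shrinks in
lines that suppress the phenotype better.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

log = logging.getLogger(__name__)


def hypergeom_enrich(
    query: set[str],
    annotations: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query set.

    Annotations are intersected with the universe; the query must be a
    subset of the universe.  Returns a frame sorted by p with columns
    term, k, K, n, N, p, adj_p.
    """
    outside = sorted(query - universe)
    if outside:
        raise ValueError(
            f"query genes outside the universe: {', '.join(outside[:10])}"
            + ("..." if len(outside) > 10 else "")
        )
    n, big_n = len(query), len(universe)
    rows = []
    for term in sorted(annotations):
        members = annotations[term] & universe
        k = len(query & members)
        big_k = len(members)
        # upper tail P(X >= k); sf(k-1) with X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "k": k, "K": big_k, "n": n, "N": big_n,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


@dataclass
class TukeyCLD:
    """One-way ANOVA + Tukey HSD + compact letter display."""

    means: pd.Series  # per-group mean, sorted descending
    anova_f: float
    anova_p: float
    tukey_p: pd.DataFrame  # symmetric matrix of pairwise adjusted p
    letters: dict[str, str]  # group -> letter string, "a" = highest mean


def anova_tukey_cld(groups: dict[str, "np.ndarray | list[float]"],
                    alpha: float = 0.05) -> TukeyCLD:
    """Compare group means; letters shared iff not significantly different.

    Letters are assigned greedily from the highest-mean group downward:
    each group joins every letter class whose members it does not differ
    from, or founds a new letter.  The result is invariant to the input
    ordering of groups.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {name: np.asarray(v, dtype=float) for name, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    names = sorted(arrays)
    f, p = stats.f_oneway(*(arrays[n] for n in names))
    res = stats.tukey_hsd(*(arrays[n] for n in names))
    tukey = pd.DataFrame(res.pvalue, index=names, columns=names)

    means = pd.Series({n: float(np.mean(arrays[n])) for n in names})
    means = means.sort_values(ascending=False, kind="stable")
    ordered = list(means.index)
    # greedy letter classes; a class is a clique of "not significantly different"
    classes: list[list[str]] = []
    for name in ordered:
        placed = False
        for cls in classes:
            if all(tukey.loc[name, other] > alpha for other in cls):
                cls.append(name)
                placed = True
        if not placed:
            classes.append([name])
    # drop classes fully contained in another (no new information)
    kept: list[list[str]] = []
    for cls in classes:
        if not any(set(cls) < set(other) for other in classes if other is not cls):
            kept.append(cls)
    letters = {n: "" for n in names}
    for i, cls in enumerate(kept):
        letter = chr(ord("a") + i)
        for n in ordered:
            if n in cls:
                letters[n] += letter
    return TukeyCLD(means=means, anova_f=float(f), anova_p=float(p),
                    tukey_p=tukey, letters=letters)


@dataclass
class FeedbackTrend:
    """Spearman trend of pathway deregulation against suppression rank."""

    mean_abs_logfc: pd.Series  # per line, ranking order
    rho: float
    p_permutation: float
    degenerate: bool  # constant means: rho undefined, reported as 0


def feedback_trend(
    de: pd.DataFrame,
    pathway_genes: set[str],
    line_ranking: list[str],
) -> FeedbackTrend:
    """Is a pathway less deregulated in better-suppressing lines?

    ``line_ranking`` orders lines from best to worst phenotypic
    suppression.  For each line the mean |logFC| over the pathway genes is
    computed (missing genes logged and skipped); the statistic is the
    Spearman correlation between suppression rank and mean |logFC|, with
    an exact permutation p-value over all orderings of the line labels
    (one-sided: trends as strong as observed).
    """
    logfc = de.pivot(index="gene", columns="line", values="logFC")
    present = sorted(pathway_genes & set(logfc.index))
    for gene in sorted(pathway_genes - set(logfc.index)):
        log.warning("pathway gene %s missing from DE table; skipped", gene)
    if not present:
        raise ValueError("no pathway gene present in the DE table")
    means = pd.Series(
        {line: float(logfc.loc[present, line].abs().mean())
         for line in line_ranking}
    )[line_ranking]
    ranks = np.arange(1, len(line_ranking) + 1, dtype=float)
    vals = means.to_numpy()
    if np.allclose(vals, vals[0]):
        return FeedbackTrend(mean_abs_logfc=means, rho=0.0,
                             p_permutation=1.0, degenerate=True)
    rho = float(stats.spearmanr(ranks, vals).statistic)
    count = 0
    total = 0
    for perm in itertools.permutations(vals):
        r = float(stats.spearmanr(ranks, np.array(perm)).statistic)
        count += r >= rho - 1e-12
        total += 1
    return FeedbackTrend(mean_abs_logfc=means, rho=rho,
                         p_permutation=count / total, degenerate=False)
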