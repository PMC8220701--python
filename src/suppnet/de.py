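"""Normalization, probe collapsing and moderated differential expression.

Each non-reference line is contrasted against the wild-type reference on
the log2 scale.  Per-gene variances are shrunk toward a common prior by an
empirical-Bayes scheme: the prior degrees of freedom ``d0`` and prior
variance ``s0^2`` are estimated from the ensemble of pooled sample
variances via the moments of ``log s_g^2`` (digamma/trigamma matching), and
the moderated t statistic uses the posterior variance

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

with ``d0 + d_g`` degrees of freedom.  A gene is called differentially
expressed when its BH-adjusted p-value is at most ``fdr_threshold`` and
|logFC| >= log2(``fc_threshold``).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import PipelineConfig
from .data import ExpressionMatrix

log = logging.getLogger(__name__)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean distribution of order statistics.

    After normalization each column's sorted values equal the across-sample
    mean of order statistics; ties within a column receive the mean of the
    quantile values they span (average-rank convention).
    """
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if values.isna().any().any():
        raise ValueError("quantile normalization does not accept NaN values")
    arr = values.to_numpy(dtype=float)
    mean_order = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, tie-averaged
        # interpolate mean order statistics at (possibly fractional) ranks
        out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), mean_order)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def collapse_probes(matrix: ExpressionMatrix,
                    probe_to_gene: dict[str, list[str] | str]) -> ExpressionMatrix:
    """Average probes per gene; probes mapping to more than one gene are dropped.

    A probe mapped to zero genes is ignored; a gene with no remaining
    probes is absent from the output.
    """
    gene_probes: dict[str, list[str]] = {}
    for probe, genes in probe_to_gene.items():
        targets = [genes] if isinstance(genes, str) else list(genes)
        if len(set(targets)) != 1:  # non-unique probe set
            continue
        if probe in matrix.values.index:
            gene_probes.setdefault(targets[0], []).append(probe)
    rows = {
        gene: matrix.values.loc[probes].mean(axis=0)
        for gene, probes in gene_probes.items()
    }
    values = pd.DataFrame(rows).T
    values = values.reindex(sorted(values.index))
    values.columns = matrix.values.columns
    log.info("collapsed %d probes to %d genes", len(probe_to_gene), len(values))
    return ExpressionMatrix(values=values, samples=matrix.samples.copy())


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good starting value for all y > 0
    for _ in range(50):
        tri = special.polygamma(1, x)
        # Newton step on the (stable) 1/trigamma scale
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + delta
        if np.all(np.abs(delta) < 1e-10 * np.maximum(x, 1.0)):
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from pooled variances on the log scale.

    Under the scaled-chi-square model, e_g = log s_g^2 - digamma(df/2) +
    log(df/2) has mean log s0^2 + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2); matching those moments gives the prior.
    Returns d0 = inf when the observed spread is at or below the sampling
    noise (all shrinkage, common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    e = np.log(positive) - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean, e_var = float(np.mean(e)), float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * float(_trigamma_inverse(excess))
    s0_sq = float(math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_de(
    matrix: ExpressionMatrix,
    line: str,
    reference_line: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-sample contrast of ``line`` against ``reference_line``.

    Returns a frame indexed by gene with columns logFC, t, p.  ``prior_df``
    overrides the estimated d0 (0 gives the ordinary pooled t test).
    """
    a = matrix.line_values(line).to_numpy(dtype=float)
    b = matrix.line_values(reference_line).to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"lines {line!r} and {reference_line!r} each need >= 2 replicates"
        )
    logfc = a.mean(axis=1) - b.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_sq = estimate_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_prior(s2, df_resid)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)
    return pd.DataFrame(
        {"logFC": logfc, "t": t, "p": p}, index=matrix.values.index
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def apply_thresholds(de: pd.DataFrame, fc_threshold: float,
                     fdr_threshold: float) -> pd.Series:
    """DE flag: adjusted p <= fdr_threshold and |logFC| >= log2(fc_threshold)."""
    bound = math.log2(fc_threshold)
    return (de["adj_p"] <= fdr_threshold) & (de["logFC"].abs() >= bound)


def de_table(matrix: ExpressionMatrix, config: PipelineConfig,
             prior_df: float | None = None) -> pd.DataFrame:
    """Full DE table over all non-reference lines.

    BH adjustment is applied per line (each contrast adjusted over all
    genes).  Columns: gene, line, logFC, t, p, adj_p, de_flag.
    """
    frames = []
    for line in config.non_reference_lines:
        res = moderated_de(matrix, line, config.reference_line, prior_df=prior_df)
        res = res.reset_index(names="gene")
        res.insert(1, "line", line)
        res["adj_p"] = bh_adjust(res["p"].to_numpy())
        res["de_flag"] = apply_thresholds(res, config.fc_threshold,
                                          config.fdr_threshold)
        log.info("DE %s vs %s: %d/%d genes flagged",
                 line, config.reference_line, int(res["de_flag"].sum()), len(res))
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def de_flag_matrix(de: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long DE table to a gene x line boolean flag matrix."""
    return de.pivot(index="gene", columns="line", values="de_flag").astype(bool)


def logfc_matrix(de: pd.DataFrame) -> pd.DataFrame:
    return de.pivot(index="gene", columns="line", values="logFC")


def pca_qc(matrix: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the first principal components (replicate QC).

    Genes are centered; scores come from the SVD of the sample x gene
    matrix.  Returns a frame indexed by sample with PC columns plus the
    sample's line, and attrs ``within_line`` / ``between_line`` dispersion
    (mean squared distance to line centroid vs between centroids).
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    x = matrix.values.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    out = pd.DataFrame(
        scores,
        index=matrix.values.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    out["line"] = matrix.samples["line"]
    centroids = out.groupby("line")[out.columns[:-1]].mean()
    within = float(
        np.mean(
            [
                np.sum((out.loc[s_, out.columns[:-1]].to_numpy(dtype=float)
                        - centroids.loc[out.loc[s_, "line"]].to_numpy()) ** 2)
                for s_ in out.index
            ]
        )
    )
    grand = centroids.to_numpy().mean(axis=0)
    between = float(np.mean(np.sum((centroids.to_numpy() - grand) ** 2, axis=1)))
    out.attrs["within_line"] = within
    out.attrs["between_line"] = between
    return out
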