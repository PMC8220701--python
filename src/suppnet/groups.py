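"""Set logic over DE flags: restored / compensatory / non-restored groups.

With a mutant line m and exactly three suppressor lines s1..s3, every gene
falls in at most one of:

* **A (restored)** — DE in m, no longer DE in at least two suppressors;
  core when not DE in all three.
* **B (compensatory)** — not DE in m, DE in at least two suppressors; core
  when DE in all three.
* **C (non-restored)** — DE in m and still DE in at least two suppressors;
  core when DE in all three.
* **D / E / F** — not DE in m, DE in exactly one designated suppressor
  (each suppressor line owns one of the three labels).

Everything else (in particular genes DE nowhere) is labelled ``none``.
Membership is purely flag-based: sign or magnitude changes that stay on
the same side of the thresholds do not matter.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GROUP_LABELS = ("A", "B", "C", "D", "E", "F")


def classify_gene(mutant_de: bool, suppressor_de: tuple[bool, bool, bool]
                  ) -> tuple[str, bool]:
    """Label one DE-flag pattern; returns (label, core)."""
    n_de = sum(suppressor_de)
    if mutant_de:
        if n_de <= 1:  # not-DE in >= 2 suppressors: restored
            return "A", n_de == 0
        return "C", n_de == 3
    if n_de >= 2:
        return "B", n_de == 3
    if n_de == 1:
        label = "DEF"[suppressor_de.index(True)]
        return label, False
    return "none", False


def classify_groups(
    de_flags: pd.DataFrame,
    mutant_line: str,
    suppressor_lines: tuple[str, str, str] | list[str],
) -> pd.DataFrame:
    """Classify every gene of a gene x line boolean flag matrix.

    ``suppressor_lines`` order fixes the D/E/F identities: the first
    suppressor owns D, the second E, the third F.  Returns a frame indexed
    by gene with columns ``label`` and ``core``.
    """
    suppressor_lines = list(suppressor_lines)
    if len(suppressor_lines) != 3:
        raise ValueError(
            f"group classification is defined for exactly 3 suppressor lines, "
            f"got {len(suppressor_lines)}"
        )
    for line in [mutant_line, *suppressor_lines]:
        if line not in de_flags.columns:
            raise ValueError(f"DE flags lack line {line!r}")
    m = de_flags[mutant_line].to_numpy(dtype=bool)
    s = de_flags[suppressor_lines].to_numpy(dtype=bool)
    labels, cores = [], []
    for i in range(len(de_flags)):
        label, core = classify_gene(bool(m[i]), tuple(s[i]))
        labels.append(label)
        cores.append(core)
    out = pd.DataFrame({"label": labels, "core": cores}, index=de_flags.index)
    counts = out["label"].value_counts()
    log.info("group sizes: %s", {k: int(counts.get(k, 0)) for k in GROUP_LABELS})
    return out


def group_sets(assignment: pd.DataFrame) -> dict[str, set[str]]:
    """Label -> gene set, plus core variants under keys 'coreA' etc."""
    out: dict[str, set[str]] = {}
    for label in GROUP_LABELS:
        mask = assignment["label"] == label
        out[label] = set(assignment.index[mask])
        out["core" + label] = set(assignment.index[mask & assignment["core"]])
    return out


def seed_genes(assignment: pd.DataFrame) -> set[str]:
    """The network-analysis seed set: union of groups A, B and C."""
    mask = assignment["label"].isin(["A", "B", "C"])
    return set(assignment.index[mask])


def marker_concordance(
    de: pd.DataFrame,
    markers: pd.DataFrame,
    mutant_line: str,
    suppressor_lines: list[str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Direction calls for literature marker genes across lines.

    Markers absent from the DE table are logged and skipped; markers not DE
    in the mutant are excluded (they cannot inform restoration).  The
    returned table has one row per retained marker with the literature
    direction and an {up, down, not-DE} call per line; the dict counts, per
    suppressor, retained markers that are restored (not DE) there.
    """
    lines = [mutant_line, *suppressor_lines]
    flags = de.pivot(index="gene", columns="line", values="de_flag")
    logfc = de.pivot(index="gene", columns="line", values="logFC")
    rows = []
    for rec in markers.itertuples(index=False):
        if rec.gene not in flags.index:
            log.warning("marker %s absent from expression data; skipped", rec.gene)
            continue
        if not bool(flags.loc[rec.gene, mutant_line]):
            continue
        row = {"gene": rec.gene, "literature": rec.direction}
        for line in lines:
            if bool(flags.loc[rec.gene, line]):
                row[line] = "up" if logfc.loc[rec.gene, line] > 0 else "down"
            else:
                row[line] = "not-DE"
        rows.append(row)
    table = pd.DataFrame(rows, columns=["gene", "literature", *lines])
    restored = {
        s: int((table[s] == "not-DE").sum()) if len(table) else 0
        for s in suppressor_lines
    }
    log.info("markers retained (DE in %s): %d; restored per suppressor: %s",
             mutant_line, len(table), restored)
    return table, restored


def relative_de_correlation(
    de: pd.DataFrame, base_line: str, line_x: str, line_y: str
) -> float:
    """Squared Pearson correlation of two lines' logFC relative to a base line.

    Each line's reference-relative logFC is re-based to ``base_line`` (the
    differences of against-reference logFCs), so the correlation is driven
    by genes whose expression changes relative to the base (mutant) line.
    """
    logfc = de.pivot(index="gene", columns="line", values="logFC")
    for line in (base_line, line_x, line_y):
        if line not in logfc.columns:
            raise ValueError(f"DE table lacks logFC for line {line!r}")
    x = (logfc[line_x] - logfc[base_line]).to_numpy(dtype=float)
    y = (logfc[line_y] - logfc[base_line]).to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    if line_x == line_y:
        return 1.0
    r, _ = stats.pearsonr(x, y)
    return float(r ** 2)
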