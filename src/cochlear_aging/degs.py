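"""Differential expression under the study's DEG rule.

A gene is differentially expressed between the two ages when it is expressed
above background in at least one age, |log2 fold change (aged/young)| >= 1,
and the Benjamini-Hochberg FDR-adjusted ANOVA p-value is <= 0.10 (both
thresholds inclusive and configurable). The per-gene test is a one-way
fixed-effects ANOVA on log2(RPKM + pseudocount); for two groups this is
identical to the pooled-variance t-test (F = t^2).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .expression import ExpressionMatrix, Thresholds, filter_expressed

__all__ = [
    "log2_fold_change",
    "two_group_anova",
    "bh_fdr",
    "classify_deg",
    "DEG_STATUSES",
    "write_deg_table",
]

DEG_STATUSES = ("up", "down", "ns", "not_expressed")

DEFAULT_PSEUDOCOUNT = 0.01


def log2_fold_change(mean_young: float, mean_aged: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((aged + pc)/(young + pc)); positive = upregulated with age."""
    if mean_young < 0 or mean_aged < 0:
        raise ConfigurationError("group means must be non-negative")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    if mean_young + pseudocount == 0 or mean_aged + pseudocount == 0:
        raise ConfigurationError(
            "log2 fold change undefined: zero mean with zero pseudocount"
        )
    return float(np.log2((mean_aged + pseudocount) / (mean_young + pseudocount)))


def _anova_arrays(young: np.ndarray, aged: np.ndarray) -> np.ndarray:
    """Vectorized two-group one-way ANOVA p-values, rows = genes.

    Degenerate rows (zero within-group variance) give p = 1 when the group
    means are equal and p = 0 otherwise.
    """
    n1, n2 = young.shape[1], aged.shape[1]
    m1, m2 = young.mean(axis=1), aged.mean(axis=1)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((young - m1[:, None]) ** 2).sum(axis=1) + ((aged - m2[:, None]) ** 2).sum(axis=1)
    df1, df2 = 1, n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(f, df1, df2)
    zero_var = ssw == 0
    p = np.where(zero_var & (ssb == 0), 1.0, p)
    p = np.where(zero_var & (ssb > 0), 0.0, p)
    return p


def two_group_anova(young_reps, aged_reps) -> float:
    """One-way fixed-effects ANOVA p for two groups (equals pooled t-test p)."""
    y = np.asarray(young_reps, dtype=float)[None, :]
    a = np.asarray(aged_reps, dtype=float)[None, :]
    if y.shape[1] < 2 or a.shape[1] < 2:
        raise ConfigurationError("need >=2 replicates per group")
    return float(_anova_arrays(y, a)[0])


def two_group_f(young_reps, aged_reps) -> float:
    """The F statistic behind :func:`two_group_anova` (equals t^2)."""
    y = np.asarray(young_reps, dtype=float)
    a = np.asarray(aged_reps, dtype=float)
    if len(y) < 2 or len(a) < 2:
        raise ConfigurationError("need >=2 replicates per group")
    n1, n2 = len(y), len(a)
    m1, m2 = y.mean(), a.mean()
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((y - m1) ** 2).sum() + ((a - m2) ** 2).sum()
    if ssw == 0:
        return math.inf if ssb > 0 else 0.0
    return float((ssb / 1) / (ssw / (n1 + n2 - 2)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ConfigurationError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_deg(
    matrix: ExpressionMatrix,
    cell_type: str,
    young_age: str,
    aged_age: str,
    thresholds: Thresholds = Thresholds(),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene DEG table and {n_deg, n_up, n_down} summary for one cell type.

    Genes expressed (mean replicate RPKM above background) in at least one
    age are tested; the BH family is exactly that tested set. Thresholds are
    inclusive: status "up" needs log2fc >= log2fc_min and fdr <= fdr_max.
    """
    young = matrix.group_values(cell_type, young_age)
    aged = matrix.group_values(cell_type, aged_age)
    if young.shape[1] < 2 or aged.shape[1] < 2:
        raise ConfigurationError("both ages need >=2 replicates")

    expressed_young, _ = filter_expressed(matrix, (cell_type, young_age), thresholds)
    expressed_aged, _ = filter_expressed(matrix, (cell_type, aged_age), thresholds)
    tested_mask = matrix.genes.isin(expressed_young | expressed_aged)

    mean_young = young.mean(axis=1)
    mean_aged = aged.mean(axis=1)
    log2fc = np.log2((mean_aged + pseudocount) / (mean_young + pseudocount))

    ylog = np.log2(young.to_numpy() + pseudocount)
    alog = np.log2(aged.to_numpy() + pseudocount)
    p_all = _anova_arrays(ylog, alog)

    p = np.full(len(matrix.genes), np.nan)
    fdr = np.full(len(matrix.genes), np.nan)
    p[tested_mask] = p_all[tested_mask]
    if tested_mask.any():
        fdr[tested_mask] = bh_fdr(p_all[tested_mask])

    status = np.full(len(matrix.genes), "ns", dtype=object)
    status[~tested_mask] = "not_expressed"
    sig = tested_mask & (fdr <= thresholds.fdr_max)
    status[sig & (log2fc >= thresholds.log2fc_min)] = "up"
    status[sig & (log2fc <= -thresholds.log2fc_min)] = "down"

    table = pd.DataFrame(
        {
            "gene": matrix.genes,
            "mean_young": mean_young.to_numpy(),
            "mean_aged": mean_aged.to_numpy(),
            "log2fc": np.asarray(log2fc),
            "p": p,
            "fdr": fdr,
            "status": status,
        }
    ).set_index("gene", drop=False)
    n_up = int((status == "up").sum())
    n_down = int((status == "down").sum())
    summary = {"n_deg": n_up + n_down, "n_up": n_up, "n_down": n_down}
    return table, summary


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
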