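"""Cochleogram survival, group statistics, and fluorescence fold changes.

Count tables give surviving inner/outer hair cells in fixed-length areas at
measured distances from the cochlear apex; survival at an aged time point is
the percentage of the baseline (young) count at the matching location.
Group comparisons use the classical pooled-variance Student t-test (Welch
available behind a flag); families of pairwise tests are corrected with the
step-down Holm-Sidak procedure. Fluorescence quantification uses integrated
density = mean gray value x signal area, summarized per target as the log2
fold change of the aged group mean over the baseline group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

__all__ = [
    "survival_percentage",
    "group_compare",
    "holm_sidak",
    "integrated_density",
    "integrated_density_foldchange",
    "GroupComparison",
]

_COUNT_COLS = {"location_um", "cell_type", "age", "count"}


def _check_counts(df: pd.DataFrame, name: str) -> None:
    missing = _COUNT_COLS - set(df.columns)
    if missing:
        raise ConfigurationError(f"{name} table missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ConfigurationError(f"{name} table has negative counts")


def survival_percentage(aged: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Percent surviving cells per (location, cell type) vs the baseline age.

    Inputs are count tables with columns location_um, cell_type, age, count.
    Every aged (location, cell_type) must exist in the baseline; a zero
    baseline count makes the percentage undefined (NaN, flagged missing).
    Output columns: location_um, cell_type, age, percent.
    """
    _check_counts(aged, "aged")
    _check_counts(baseline, "baseline")
    base = baseline.set_index(["location_um", "cell_type"])["count"]
    if base.index.duplicated().any():
        raise ConfigurationError("baseline has duplicate (location, cell_type) rows")
    rows = []
    for _, r in aged.iterrows():
        key = (r["location_um"], r["cell_type"])
        if key not in base.index:
            raise ConfigurationError(
                f"no baseline count for location {key[0]} um, cell type {key[1]!r}"
            )
        b = base[key]
        pct = np.nan if b == 0 else 100.0 * r["count"] / b
        rows.append(
            {
                "location_um": r["location_um"],
                "cell_type": r["cell_type"],
                "age": r["age"],
                "percent": pct,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float


def group_compare(group_a, group_b, welch: bool = False) -> GroupComparison:
    """Two-sided t-test (pooled-variance Student by default) with group stats."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("need >=2 values per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        p=float(p),
    )


def holm_sidak(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values, mapped back to input order.

    Sorted ascending, adj_(k) = max_{j<=k} 1-(1-p_(j))^(m-j+1), clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ConfigurationError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def integrated_density(mean_gray, area) -> np.ndarray:
    """Integrated density = mean gray value x signal area."""
    return np.asarray(mean_gray, dtype=float) * np.asarray(area, dtype=float)


def integrated_density_foldchange(
    aged: pd.DataFrame, baseline: pd.DataFrame
) -> pd.DataFrame:
    """Per (target, cell_type) log2 fold change of mean integrated density.

    Inputs are per-cell quantification tables with columns target,
    cell_type, mean_gray, area (one row per measured cell). Every aged
    (target, cell_type) pair must be present in the baseline; a zero
    baseline mean is an undefined-value error. Output columns: target,
    cell_type, log2fc, n_aged, n_baseline.
    """
    for df, name in ((aged, "aged"), (baseline, "baseline")):
        missing = {"target", "cell_type", "mean_gray", "area"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"{name} table missing columns: {sorted(missing)}")

    def grouped(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out["integrated_density"] = integrated_density(out["mean_gray"], out["area"])
        return out.groupby(["target", "cell_type"])["integrated_density"].agg(["mean", "size"])

    ga, gb = grouped(aged), grouped(baseline)
    rows = []
    for key, row in ga.iterrows():
        if key not in gb.index:
            raise ConfigurationError(f"no baseline measurements for {key}")
        base_mean = gb.loc[key, "mean"]
        if base_mean == 0:
            raise ConfigurationError(f"zero baseline integrated density for {key}")
        rows.append(
            {
                "target": key[0],
                "cell_type": key[1],
                "log2fc": float(np.log2(row["mean"] / base_mean)),
                "n_aged": int(row["size"]),
                "n_baseline": int(gb.loc[key, "size"]),
            }
        )
    return pd.DataFrame(rows)
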