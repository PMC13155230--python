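"""Descriptive cohort comparisons across molecular subtypes.

Categorical characteristics are compared with Pearson's chi-square test
(no continuity correction) and continuous ones with the Kruskal-Wallis
rank test, mirroring standard cohort-description tables. "Missing" levels
are rendered in summaries but excluded from tests by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyResult", "DegenerateTableError", "chisq_test",
           "kruskal_wallis", "describe_cohort"]


class DegenerateTableError(ValueError):
    """Raised when a contingency table has a zero margin or too few groups."""


@dataclass
class ContingencyResult:
    statistic: float
    df: int
    p_value: float
    method: str  # "pearson_chisq" | "kruskal_wallis"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def chisq_test(table, monte_carlo: bool = False, n_sim: int = 10_000,
               seed: int | None = None) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction is applied. With ``monte_carlo``, the p-value is
    instead estimated by simulating tables from the margin-conditional
    multinomial null (useful when expected counts are small).

    Raises
    ------
    DegenerateTableError
        If any row or column margin is zero (naming the margin), or the table
        is smaller than 2 x 2.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateTableError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    row_margins = t.sum(axis=1)
    col_margins = t.sum(axis=0)
    for axis, margins in (("row", row_margins), ("column", col_margins)):
        zero = np.flatnonzero(margins == 0)
        if zero.size:
            raise DegenerateTableError(f"zero {axis} margin at index {zero[0]}")

    res = stats.chi2_contingency(t, correction=False)
    stat, p, df = float(res.statistic), float(res.pvalue), int(res.dof)
    if monte_carlo:
        rng = np.random.default_rng(seed)
        n = int(t.sum())
        probs = np.outer(row_margins, col_margins).ravel() / n**2
        sims = rng.multinomial(n, probs, size=n_sim).reshape(n_sim, *t.shape)
        # each simulated table is scored against its own margins
        rm = sims.sum(axis=2, keepdims=True)
        cm = sims.sum(axis=1, keepdims=True)
        expected = rm * cm / n
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(expected > 0, (sims - expected) ** 2 / expected, 0.0)
        sim_stats = contrib.sum(axis=(1, 2))
        p = float((np.count_nonzero(sim_stats >= stat - 1e-12) + 1) / (n_sim + 1))
    return ContingencyResult(stat, df, p, "pearson_chisq")


def kruskal_wallis(values, groups) -> ContingencyResult:
    """Kruskal-Wallis H test (tie-corrected) of a continuous row across groups.

    With all observations equal, the tie correction is degenerate and the
    statistic is reported as 0 with p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    samples = [s for s in samples if len(s)]
    if len(samples) < 2:
        raise DegenerateTableError("need at least 2 non-empty groups")
    df = len(samples) - 1
    if np.ptp(values) == 0:  # all equal: H = 0/0 under tie correction
        return ContingencyResult(0.0, df, 1.0, "kruskal_wallis")
    stat, p = stats.kruskal(*samples)
    return ContingencyResult(float(stat), df, float(p), "kruskal_wallis")


_CONTINUOUS = ("age_dx", "tslb", "bmi")


def describe_cohort(cohort: pd.DataFrame, by: str = "subtype",
                    include_missing: bool = False) -> pd.DataFrame:
    """Cohort-description table: per-group summaries plus a per-row test.

    Categorical variables get counts with percentages (column-wise within
    group) and a chi-square p; continuous variables get mean (SD) and a
    Kruskal-Wallis p. Missing values are shown as their own level but
    excluded from tests unless ``include_missing`` (which treats missingness
    as a category; continuous rows always drop missing values).
    """
    if by not in cohort.columns:
        raise KeyError(f"grouping variable {by!r} not in cohort")
    groups = cohort[by].astype(object).where(cohort[by].notna(), "Missing")
    group_levels = [g for g in pd.unique(groups)]
    rows = []
    for col in cohort.columns:
        if col in ("woman_id", by):
            continue
        if col in _CONTINUOUS or pd.api.types.is_float_dtype(cohort[col]):
            vals = cohort[col].astype(float)
            try:
                test = kruskal_wallis(vals.to_numpy(), groups.to_numpy())
                p = test.p_value
            except DegenerateTableError:
                p = np.nan
            for g in group_levels:
                sub = vals[groups == g].dropna()
                rows.append({"variable": col, "level": "mean (SD)", "group": g,
                             "value": f"{sub.mean():.2f} ({sub.std():.2f})",
                             "p_value": p})
        else:
            levels = cohort[col].astype(object).where(cohort[col].notna(), "Missing")
            tab = pd.crosstab(levels, groups)
            test_tab = tab
            if not include_missing:
                test_tab = tab.drop(index="Missing", errors="ignore")
                test_tab = test_tab.loc[:, (test_tab.sum(axis=0) > 0)]
            try:
                p = chisq_test(test_tab.to_numpy()).p_value
            except DegenerateTableError:
                p = np.nan
            totals = tab.sum(axis=0)
            for lev in tab.index:
                for g in tab.columns:
                    n = int(tab.loc[lev, g])
                    pct = 100.0 * n / totals[g] if totals[g] else 0.0
                    rows.append({"variable": col, "level": str(lev), "group": g,
                                 "value": f"{n} ({pct:.1f}%)", "p_value": p})
    return pd.DataFrame(rows)
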