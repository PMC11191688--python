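"""Univariate screen: normality check, Mann-Whitney tests, fold changes.

Per-group normality is reported with Shapiro-Wilk but is informational only;
group comparisons are always the nonparametric Mann-Whitney U test, two-sided,
with no multiple-testing correction — matching the study's reporting
convention (p < 0.05 flagged "*", 0.05 <= p < 0.1 flagged "#").

With 7-8 animals per arm the exact null distribution of U is computed for
tie-free samples (n1, n2 <= 8); larger or tied samples fall back to the
normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Comparison, DEFAULT_COMPARISONS, SampleTable
from .errors import ConfigurationError, DataError, DegenerateSampleError
from .expression import fold_change

#: per-group sample size at or below which the exact U distribution is used
EXACT_N_MAX = 8


def flag_for_p(p: float) -> str:
    """Significance flag: '*' for p<0.05, '#' for 0.05<=p<0.1, else ''."""
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "#"
    return ""


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one group's values (3 <= n <= 5000)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or arr.size > 5000:
        raise DataError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={arr.size}")
    if not np.all(np.isfinite(arr)):
        raise DataError("Shapiro-Wilk requires finite values")
    if np.ptp(arr) == 0.0:
        raise DegenerateSampleError("constant sample: normality test undefined")
    res = stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact p (full permutation null of U) when both groups have <= 8
    observations and the pooled sample is tie-free; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise DataError("Mann-Whitney requires non-empty groups")
    if xa.size < 3 or ya.size < 3:
        raise DataError(
            f"Mann-Whitney requires n >= 3 per group, got {xa.size} and {ya.size}"
        )
    pooled = np.concatenate([xa, ya])
    if not np.all(np.isfinite(pooled)):
        raise DataError("Mann-Whitney requires finite values")
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and xa.size <= EXACT_N_MAX and ya.size <= EXACT_N_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    comparison: str
    test: str
    reference: str
    u: float
    p: float
    fc: float
    flag: str


def pairwise_screen(
    table: SampleTable,
    comparisons: Sequence[Comparison] = DEFAULT_COMPARISONS,
) -> pd.DataFrame:
    """Mann-Whitney + fold change for every variable x comparison.

    Returns a tidy frame with columns ``variable, comparison, test,
    reference, U, p, fc, flag`` — one row per variable per comparison.
    """
    present = set(table.groups)
    for cmp_ in comparisons:
        missing = {cmp_.test, cmp_.reference} - present
        if missing:
            raise ConfigurationError(f"unknown group label(s): {sorted(missing)}")
    rows: list[UnivariateResult] = []
    for cmp_ in comparisons:
        test_mask = table.groups == cmp_.test
        ref_mask = table.groups == cmp_.reference
        for var in table.variables:
            xv = table.data.loc[test_mask, var].dropna().to_numpy()
            yv = table.data.loc[ref_mask, var].dropna().to_numpy()
            u, p = mann_whitney(xv, yv)
            fc = fold_change(table, var, cmp_.test, cmp_.reference).fc
            rows.append(
                UnivariateResult(
                    variable=var,
                    comparison=cmp_.label,
                    test=cmp_.test,
                    reference=cmp_.reference,
                    u=u,
                    p=p,
                    fc=fc,
                    flag=flag_for_p(p),
                )
            )
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["variable", "comparison", "test", "reference", "u", "p", "fc", "flag"],
    ).rename(columns={"u": "U"})


def normality_report(table: SampleTable) -> pd.DataFrame:
    """Shapiro-Wilk W and p per variable per group (informational)."""
    rows = []
    for grp in table.group_labels:
        mask = table.groups == grp
        for var in table.variables:
            vals = table.data.loc[mask, var].dropna().to_numpy()
            try:
                w, p = shapiro_wilk(vals)
            except DataError:
                w, p = np.nan, np.nan
            rows.append((var, grp, w, p))
    return pd.DataFrame(rows, columns=["variable", "group", "W", "p"])
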