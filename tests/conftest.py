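"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (full enumeration, hand-computed
ranks, brute-force chord distances) so they stay independent of the library
code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dietsel import Comparison, SampleTable, StudyConfig, generate_study
from dietsel.synthetic import plant_effects


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def mann_whitney_bruteforce(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group labelings.

    Builds the full null distribution of U over every C(n1+n2, n1) way of
    assigning the pooled (tie-free) values to group x, then returns
    p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    dist: dict[int, int] = {}
    for idx in itertools.combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in set(idx)]
        u = u_stat(xs, ys)
        dist[u] = dist.get(u, 0) + 1
    total = math.comb(n1 + n2, n1)
    p_le = sum(c for u, c in dist.items() if u <= u_obs) / total
    p_ge = sum(c for u, c in dist.items() if u >= u_obs) / total
    return float(u_obs), min(1.0, 2.0 * min(p_le, p_ge))


def midranks(values) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    arr = np.asarray(values, dtype=float)
    order = np.argsort(arr, kind="mergesort")
    ranks = np.empty(arr.size, dtype=float)
    i = 0
    while i < arr.size:
        j = i
        while j + 1 < arr.size and arr[order[j + 1]] == arr[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_bruteforce(x, y) -> tuple[float, float]:
    """Pearson correlation of hand-computed mid-ranks + t-approximation p."""
    from scipy.stats import t as t_dist

    rx, ry = midranks(x), midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(rx)
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * t_dist.sf(abs(t), n - 2))


def chord_distance_argmax(sorted_totals) -> int:
    """Brute-force knee: maximal perpendicular distance to the endpoint chord
    of the unit-square-normalized curve. Returns the 0-based index."""
    y = np.asarray(sorted_totals, dtype=float)
    n = y.size
    x = np.arange(n) / (n - 1)
    y = (y - y[-1]) / (y[0] - y[-1])
    # chord from (0, 1) to (1, 0): x + y - 1 = 0
    dist = np.abs(x + y - 1.0) / math.sqrt(2.0)
    below = (x + y - 1.0) < 0  # knees of a decreasing curve lie below the chord
    dist[~below] = -np.inf
    return int(np.argmax(dist))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig(master_seed=11)


@pytest.fixture(scope="session")
def null_table(default_config) -> SampleTable:
    """Default study with no planted effects (null model)."""
    return generate_study(default_config)


@pytest.fixture(scope="session")
def planted_config() -> StudyConfig:
    """Eight planted discriminators at d=2 for Tenebrio vs Control."""
    base = StudyConfig(master_seed=7)
    names = base.variable_names()
    chosen = [names[i] for i in (0, 5, 12, 30, 45, 52, 60, 70)]
    return plant_effects(base, chosen, ("Tenebrio",), d=2.0)


@pytest.fixture(scope="session")
def planted_table(planted_config) -> SampleTable:
    return generate_study(planted_config)


@pytest.fixture
def tiny_table() -> SampleTable:
    """Hand-built 8-sample, 4-variable table for exact-value tests."""
    data = pd.DataFrame(
        {
            "metabolic_01": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            "metabolic_02": [2.0, 2.0, 2.0, 2.0, 4.0, 4.0, 4.0, 4.0],
            "tasr_expression_01": [1.0, 1.2, 0.9, 1.1, 2.0, 2.2, 1.9, 2.1],
            "inflammatory_01": [5.0, 6.0, 5.5, 6.5, 5.2, 6.2, 5.7, 6.7],
        },
        index=[f"s{i}" for i in range(8)],
    )
    groups = pd.Series(
        ["Control"] * 4 + ["Tenebrio"] * 4, index=data.index, name="group"
    )
    ann = pd.DataFrame(
        {
            "block": ["metabolic", "metabolic", "tasr_expression", "inflammatory"],
            "segment": ["none", "none", "AC", "plasma"],
        },
        index=pd.Index(data.columns, name="variable"),
    )
    return SampleTable(data=data, groups=groups, annotations=ann)


@pytest.fixture(scope="session")
def tenebrio_vs_control() -> Comparison:
    return Comparison("Tenebrio", "Control", "healthy")
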