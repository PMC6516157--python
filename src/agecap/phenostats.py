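"""Organismal statistics: exact contingency tests, localization scores,
Kaplan-Meier lifespan curves and the log-rank comparison.

The 2 x c Fisher exact test enumerates every table with the observed margins;
the two-sided p-value is the total probability of tables no more probable
than the observed one (the common convention).  Localization tables score
each worm 0 (cytoplasmic), 1 (weakly nuclear) or 2 (strongly nuclear).
Lifespan comparisons use the product-limit estimator and the standard 1-df
log-rank chi-square; mean lifespan is the restricted mean over the observed
event horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .errors import ContractViolation

ENUMERATION_BOUND = 500
NUCLEAR_SCORES = (0, 1, 2)


def fisher_exact_rx_c(table: np.ndarray | list[list[int]]) -> float:
    """Two-sided Fisher exact p for a 2 x c table (c in {2, 3}) by enumeration."""
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] not in (2, 3):
        raise ContractViolation("fisher_exact_rx_c expects a 2x2 or 2x3 table")
    if (table < 0).any():
        raise ContractViolation("counts must be non-negative")
    total = int(table.sum())
    if total > ENUMERATION_BOUND:
        raise ContractViolation(
            f"total count {total} exceeds the enumeration bound {ENUMERATION_BOUND}; "
            "use chi_square_test instead"
        )
    col_sums = table.sum(axis=0)
    r1 = int(table[0].sum())
    denom = comb(total, r1)

    def prob(row: tuple[int, ...]) -> float:
        p = 1.0
        for a, c in zip(row, col_sums):
            p *= comb(int(c), a)
        return p / denom

    p_obs = prob(tuple(int(v) for v in table[0]))

    # enumerate first-row allocations with fixed margins
    def allocations(remaining_cols: list[int], remaining: int):
        if len(remaining_cols) == 1:
            if 0 <= remaining <= remaining_cols[0]:
                yield (remaining,)
            return
        head, *tail = remaining_cols
        tail_cap = sum(tail)
        for a in range(max(0, remaining - tail_cap), min(head, remaining) + 1):
            for rest in allocations(tail, remaining - a):
                yield (a, *rest)

    p_value = 0.0
    tolerance = 1 + 1e-9
    for row in allocations([int(c) for c in col_sums], r1):
        p = prob(row)
        if p <= p_obs * tolerance:
            p_value += p
    return min(1.0, p_value)


def chi_square_test(table: np.ndarray | list[list[int]]) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; returns (statistic, p)."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ContractViolation("chi-square test requires positive row and column margins")
    statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p)


def mean_nuclear_score(row: np.ndarray | list[int], scores=NUCLEAR_SCORES) -> float:
    """Count-weighted mean ordinal localization score (NaN for an empty row)."""
    row = np.asarray(row, dtype=float)
    n = row.sum()
    if n == 0:
        return float("nan")
    return float(np.dot(row, np.asarray(scores, dtype=float)) / n)


def collapse_nuclear(table: np.ndarray | list[list[int]]) -> np.ndarray:
    """Merge the weakly- and strongly-nuclear categories of a 2x3 table."""
    table = np.asarray(table, dtype=int)
    return np.column_stack([table[:, 0], table[:, 1] + table[:, 2]])


def percent_reduction(mean_a: float, mean_b: float) -> float:
    """100 * (mean_a - mean_b) / mean_a, e.g. 19.1 vs 17.8 days -> 6.8%."""
    if mean_a == 0:
        raise ContractViolation("reference mean lifespan is zero")
    return 100.0 * (mean_a - mean_b) / mean_a


def _restricted_mean(times: np.ndarray, survival: np.ndarray, horizon: float) -> float:
    """Integrate a right-continuous KM step function from 0 to ``horizon``."""
    grid = np.concatenate([[0.0], times[times <= horizon], [horizon]])
    grid = np.unique(grid)
    area = 0.0
    s = 1.0
    for left, right in zip(grid[:-1], grid[1:]):
        area += s * (right - left)
        step = survival[times == right]
        if step.size:
            s = float(step[0])
    return area


@dataclass
class KMComparison:
    curves: dict[str, pd.DataFrame]  # per group: columns time, survival
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    pct_reduction: float


def km_logrank(records: pd.DataFrame, group_a: str, group_b: str) -> KMComparison:
    """Kaplan-Meier curves, log-rank test, restricted-mean lifespans.

    Means are restricted to the last observed (uncensored) event across both
    groups; ``pct_reduction`` is relative to ``group_a``.
    """
    curves: dict[str, pd.DataFrame] = {}
    durations: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    for label in (group_a, group_b):
        sub = records[records["group"] == label]
        if sub.empty:
            raise ContractViolation(f"group {label!r} has no records")
        durations[label] = sub["day_of_death"].to_numpy(dtype=float)
        observed[label] = 1 - sub["censored"].to_numpy(dtype=int)
        if observed[label].sum() < 2:
            raise ContractViolation(f"group {label!r} has fewer than 2 uncensored events")

    horizon = max(
        durations[g][observed[g] == 1].max() for g in (group_a, group_b)
    )
    means: dict[str, float] = {}
    for label in (group_a, group_b):
        fitter = KaplanMeierFitter()
        fitter.fit(durations[label], event_observed=observed[label], label=label)
        sf = fitter.survival_function_
        times = sf.index.to_numpy(dtype=float)
        surv = sf[label].to_numpy(dtype=float)
        curves[label] = pd.DataFrame({"time": times, "survival": surv})
        means[label] = _restricted_mean(times, surv, horizon)

    test = logrank_test(
        durations[group_a],
        durations[group_b],
        event_observed_A=observed[group_a],
        event_observed_B=observed[group_b],
    )
    return KMComparison(
        curves=curves,
        statistic=float(test.test_statistic),
        p_value=float(test.p_value),
        mean_a=means[group_a],
        mean_b=means[group_b],
        pct_reduction=percent_reduction(means[group_a], means[group_b]),
    )
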