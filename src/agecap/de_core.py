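"""Negative-binomial Wald differential expression between two sample groups.

Normalization uses the median-of-ratios convention: each sample's factor is
the median over genes of its count divided by the gene's geometric-mean
reference (genes with a zero anywhere are excluded from the reference).

Per-gene dispersion alpha (variance = mu + alpha * mu^2) is a method-of-moments
estimate from within-group normalized counts, floored, then averaged with a
fitted mean-dispersion trend alpha(mu) = a1/mu + a0 (fixed weight 0.5) — a
deliberately simple, documented stand-in for heavier shrinkage machinery whose
calibration is asserted by simulation rather than by bit-compatibility.

The contrast itself uses closed-form two-group mean estimates on normalized
counts (pseudo-count 0.5 when a group mean is zero), a delta-method standard
error on the log2 fold change, and a two-sided standard-normal reference for
the Wald statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation, NormalizationError

LN2 = np.log(2.0)
ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0
TREND_SHRINK_WEIGHT = 0.5


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group contrast defined by equality predicates on sheet columns.

    ``group_a`` / ``group_b`` map sample-sheet columns to a required value or
    to a collection of admissible values, e.g. ``{"genotype": "WT", "day": 6}``.
    The reported log2 fold change is A over B.
    """

    name: str
    group_a: Mapping[str, object]
    group_b: Mapping[str, object]


@dataclass(frozen=True)
class DEGSet:
    """Up/down differentially expressed gene sets for one contrast."""

    name: str
    up: frozenset[str]
    down: frozenset[str]
    alpha: float

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


def select_samples(sheet: pd.DataFrame, predicate: Mapping[str, object]) -> list[str]:
    """Sample ids matching every column predicate (scalar or collection)."""
    mask = np.ones(len(sheet), dtype=bool)
    for column, wanted in predicate.items():
        if column not in sheet.columns:
            raise ContractViolation(f"sample sheet has no column {column!r}")
        values = sheet[column]
        if isinstance(wanted, (list, tuple, set, frozenset)):
            mask &= values.isin(list(wanted)).to_numpy()
        else:
            mask &= (values == wanted).to_numpy()
    return sheet.loc[mask, "sample_id"].tolist()


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference."""
    values = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(values)
    log_ref = log_counts.mean(axis=1)
    usable = np.isfinite(log_ref)
    if not usable.any():
        raise NormalizationError(
            "no usable reference genes: every gene has a zero count in some sample"
        )
    log_ratios = log_counts[usable] - log_ref[usable, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _fit_dispersion_trend(mean: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha = a1/mean + a0 on genes with positive mean."""
    ok = mean > 0
    x = 1.0 / mean[ok]
    y = alpha_mom[ok]
    design = np.column_stack([x, np.ones_like(x)])
    (a1, a0), *_ = np.linalg.lstsq(design, y, rcond=None)
    return max(float(a1), ALPHA_MIN), max(float(a0), ALPHA_MIN)


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: Mapping[str, object] | pd.Series,
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Per-gene NB dispersion from within-group normalized counts.

    ``groups`` maps sample id -> group label; every group must have >= 2
    samples.  All-zero genes are assigned the trend value at the median
    positive mean.
    """
    groups = pd.Series(groups)
    labels = groups.loc[counts.columns]
    y = counts.to_numpy(dtype=float) / size_factors.loc[counts.columns].to_numpy()

    mean = y.mean(axis=1)
    ss = np.zeros(counts.shape[0])
    dof = 0
    for label in labels.unique():
        cols = np.flatnonzero((labels == label).to_numpy())
        if cols.size < 2:
            raise ContractViolation(f"group {label!r} has fewer than 2 samples")
        sub = y[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += cols.size - 1
    within_var = ss / dof

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (within_var - mean) / mean**2
    alpha_mom = np.where(mean > 0, alpha_mom, np.nan)
    alpha_mom = np.clip(alpha_mom, alpha_min, ALPHA_MAX)

    a1, a0 = _fit_dispersion_trend(mean, np.nan_to_num(alpha_mom, nan=alpha_min))
    pseudo_mean = np.median(mean[mean > 0]) if (mean > 0).any() else 1.0
    trend = a1 / np.where(mean > 0, mean, pseudo_mean) + a0

    alpha = TREND_SHRINK_WEIGHT * np.nan_to_num(alpha_mom, nan=0.0) + (
        1 - TREND_SHRINK_WEIGHT
    ) * trend
    alpha = np.where(np.isnan(alpha_mom), trend, alpha)  # all-zero genes: trend only
    alpha = np.clip(alpha, alpha_min, ALPHA_MAX)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def wald_contrast(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    spec: ContrastSpec,
    size_factors: pd.Series,
    alphas: pd.Series,
) -> pd.DataFrame:
    """Two-group NB Wald test for every gene.

    Returns a DataFrame indexed by gene with columns log2_fc, se, wald_stat,
    p_raw, p_adj (BH) and mean_norm_count.  Genes with zero counts in all
    samples of both groups get log2_fc 0 and p_raw 1.
    """
    ids_a = select_samples(sheet, spec.group_a)
    ids_b = select_samples(sheet, spec.group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ContractViolation(
            f"contrast {spec.name!r}: each group needs >= 2 samples "
            f"(got {len(ids_a)} vs {len(ids_b)})"
        )
    if set(ids_a) & set(ids_b):
        raise ContractViolation(f"contrast {spec.name!r}: groups overlap")
    missing = (set(ids_a) | set(ids_b)) - set(counts.columns)
    if missing:
        raise ContractViolation(f"contrast {spec.name!r}: samples absent from counts: {sorted(missing)}")

    sf_a = size_factors.loc[ids_a].to_numpy()
    sf_b = size_factors.loc[ids_b].to_numpy()
    if (sf_a <= 0).any() or (sf_b <= 0).any():
        raise ContractViolation("size factors must be positive")
    alpha = alphas.loc[counts.index].to_numpy()

    raw_a = counts[ids_a].to_numpy(dtype=float)
    raw_b = counts[ids_b].to_numpy(dtype=float)
    y_a = raw_a / sf_a
    y_b = raw_b / sf_b
    mu_a = y_a.mean(axis=1)
    mu_b = y_b.mean(axis=1)
    all_zero = (raw_a.sum(axis=1) == 0) & (raw_b.sum(axis=1) == 0)

    # pseudo-count 0.5 keeps the estimate finite when one group is silent
    mu_a_adj = np.where(mu_a > 0, mu_a, 0.5)
    mu_b_adj = np.where(mu_b > 0, mu_b, 0.5)
    log2_fc = np.log2(mu_a_adj / mu_b_adj)

    # Var(mean of count/sf) under NB with per-sample scaling
    var_a = (mu_a_adj[:, None] / sf_a[None, :] + alpha[:, None] * mu_a_adj[:, None] ** 2).sum(
        axis=1
    ) / len(ids_a) ** 2
    var_b = (mu_b_adj[:, None] / sf_b[None, :] + alpha[:, None] * mu_b_adj[:, None] ** 2).sum(
        axis=1
    ) / len(ids_b) ** 2
    se = np.sqrt(var_a / mu_a_adj**2 + var_b / mu_b_adj**2) / LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2_fc / se, 0.0)
    p_raw = 2.0 * stats.norm.sf(np.abs(wald))

    log2_fc[all_zero] = 0.0
    wald[all_zero] = 0.0
    p_raw[all_zero] = 1.0
    se = np.where(all_zero, np.nan, se)

    result = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "se": se,
            "wald_stat": wald,
            "p_raw": p_raw,
            "p_adj": adjust_bh(p_raw),
            "mean_norm_count": np.hstack([y_a, y_b]).mean(axis=1),
        },
        index=counts.index,
    )
    result.attrs["name"] = spec.name
    return result


def adjust_bh(p_raw: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ContractViolation("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_degs(result: pd.DataFrame, alpha: float) -> DEGSet:
    """Split genes with p_adj strictly below ``alpha`` by fold-change sign."""
    if not 0 < alpha < 1:
        raise ContractViolation("alpha must lie in (0, 1)")
    significant = result["p_adj"] < alpha
    up = frozenset(result.index[significant & (result["log2_fc"] > 0)])
    down = frozenset(result.index[significant & (result["log2_fc"] < 0)])
    return DEGSet(name=result.attrs.get("name", ""), up=up, down=down, alpha=alpha)
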