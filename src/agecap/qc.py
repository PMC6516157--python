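"""Replicate-quality screening via Spearman correlation of normalized expression.

The screen mirrors what a sample dendrogram shows: a corrupted sample
correlates with nothing, while every genuine sample has at least one
near-duplicate (its within-cell replicates, or failing that a neighbouring
day).  A sample is therefore flagged when its best Spearman rho to any other
sample falls below ``min_rho`` (default 0.9).  Correlations are computed on
log2(normalized count + 1), which is rank-stable and conventional.

A per-replicate median-within-cell score is also reported for diagnostics,
but with triplicate cells it is not robust — a single corrupted replicate
drags both neighbours' medians down — so it does not drive the flagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation


def spearman_matrix(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Pairwise Spearman rho between samples on log-scale normalized counts.

    A constant sample yields undefined correlations, recorded as NaN (the
    outlier screen auto-flags such samples); the diagonal is always 1.
    """
    if counts.shape[1] < 2:
        raise ContractViolation("need at least 2 samples for a correlation matrix")
    log_expr = np.log2(
        counts.to_numpy(dtype=float) / size_factors.loc[counts.columns].to_numpy() + 1.0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(log_expr, axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if rho.shape == (1, 1):  # spearmanr collapses the 2-sample case to a scalar
        value = float(rho[0, 0])
        rho = np.array([[1.0, value], [value, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=counts.columns, columns=counts.columns)


@dataclass
class OutlierReport:
    """Result of the replicate-outlier screen."""

    flagged: list[str]
    best_rho: pd.Series
    median_rho: pd.Series
    low_confidence_cells: list[tuple[object, object]] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        flagged = set(self.flagged)
        return [s for s in self.best_rho.index if s not in flagged]


def flag_outliers(
    corr: pd.DataFrame, sheet: pd.DataFrame, min_rho: float = 0.9
) -> OutlierReport:
    """Flag samples whose best Spearman rho to any other sample is below ``min_rho``.

    Every (genotype, day) cell must start with >= 2 samples.  A cell left with
    fewer than 2 samples after dropping is reported as low-confidence with a
    warning (downstream contrasts that need it are skipped); the flagged
    samples stay flagged.  Samples with undefined correlations (constant
    expression) are always flagged.
    """
    sheet = sheet.set_index("sample_id", drop=False)
    best: dict[str, float] = {}
    medians: dict[str, float] = {}
    flagged: list[str] = []
    for sample in corr.index:
        row = sheet.loc[sample]
        mates = sheet.index[
            (sheet["genotype"] == row["genotype"])
            & (sheet["day"] == row["day"])
            & (sheet.index != sample)
        ]
        if len(mates) == 0:
            raise ContractViolation(
                f"sample {sample!r}: its (genotype, day) cell has fewer than 2 samples"
            )
        others = corr.loc[sample].drop(sample).to_numpy(dtype=float)
        top = float(np.nanmax(others)) if np.isfinite(others).any() else np.nan
        cell_rhos = corr.loc[sample, mates].to_numpy(dtype=float)
        best[sample] = top
        medians[sample] = (
            float(np.nanmedian(cell_rhos)) if np.isfinite(cell_rhos).any() else np.nan
        )
        if not np.isfinite(top) or top < min_rho:
            flagged.append(sample)

    low_confidence: list[tuple[object, object]] = []
    flagged_set = set(flagged)
    for (genotype, day), cell in sheet.groupby(["genotype", "day"]):
        remaining = [s for s in cell.index if s not in flagged_set]
        if len(remaining) < 2 and flagged_set & set(cell.index):
            warnings.warn(
                f"dropping outliers leaves cell ({genotype}, day {day}) with "
                f"{len(remaining)} samples; cell marked low-confidence",
                stacklevel=2,
            )
            low_confidence.append((genotype, day))

    return OutlierReport(
        flagged=flagged,
        best_rho=pd.Series(best, name="best_rho"),
        median_rho=pd.Series(medians, name="median_within_cell_rho"),
        low_confidence_cells=low_confidence,
    )
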