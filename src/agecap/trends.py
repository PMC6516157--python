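"""Temporal-profile analytics: Z-scoring, k-means clustering, percentile bands.

Each gene's normalized counts are standardized across ALL samples (both
genotypes, every day, per-sample columns retained) to mean 0 and unit sample
variance.  Clustering uses Lloyd k-means with k-means++ seeding from an
explicit seed — defaults of 6 clusters and at most 1,000 iterations — and the
band summaries report the 50th, 20th and 80th percentiles of the Z-score
distribution per (genotype, day), with linear interpolation between closest
ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ContractViolation


@dataclass
class TemporalProfile:
    """Row-standardized expression with the original moments retained."""

    z: pd.DataFrame
    mean: pd.Series
    variance: pd.Series
    excluded: list[str] = field(default_factory=list)


def zscore_profiles(
    norm_counts: pd.DataFrame, genes: Iterable[str] | None = None
) -> TemporalProfile:
    """Standardize each gene row across all samples (ddof=1).

    Constant rows are excluded and listed in the result.  Applying the
    transform twice is a no-op.
    """
    sub = norm_counts.loc[list(genes)] if genes is not None else norm_counts
    if sub.empty:
        raise ContractViolation("no genes selected for Z-scoring")
    values = sub.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    z = (values[keep] - mean[keep, None]) / sd[keep, None]
    return TemporalProfile(
        z=pd.DataFrame(z, index=sub.index[keep], columns=sub.columns),
        mean=pd.Series(mean[keep], index=sub.index[keep], name="mean"),
        variance=pd.Series(sd[keep] ** 2, index=sub.index[keep], name="variance"),
        excluded=list(sub.index[~keep]),
    )


@dataclass
class ClusterResult:
    labels: pd.Series  # 1..k
    centroids: pd.DataFrame
    wcss: float
    iterations: int
    seed: int


def kmeans_profiles(
    profile: TemporalProfile, k: int = 6, max_iter: int = 1000, seed: int = 0
) -> ClusterResult:
    """Lloyd k-means (k-means++ seeding, one start, fixed seed) on Z-scores."""
    n_genes = profile.z.shape[0]
    if k < 1 or k > n_genes:
        raise ContractViolation(f"k={k} outside [1, {n_genes}]")
    model = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(profile.z.to_numpy())
    labels = pd.Series(model.labels_ + 1, index=profile.z.index, name="cluster")
    centroids = pd.DataFrame(
        model.cluster_centers_,
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=profile.z.columns,
    )
    return ClusterResult(
        labels=labels,
        centroids=centroids,
        wcss=float(model.inertia_),
        iterations=int(model.n_iter_),
        seed=seed,
    )


def percentile_bands(
    profile: TemporalProfile,
    sheet: pd.DataFrame,
    percentiles: Sequence[float] = (20, 50, 80),
) -> pd.DataFrame:
    """Z-score percentiles per (genotype, day) over all genes and replicates.

    Percentiles use linear interpolation between closest ranks (the numpy
    default).  Groups without samples yield missing entries.
    """
    sheet = sheet.set_index("sample_id")
    rows = []
    for (genotype, day), cell in sheet.groupby(["genotype", "day"]):
        cols = [s for s in cell.index if s in profile.z.columns]
        row: dict[str, object] = {"genotype": genotype, "day": day}
        if cols:
            values = profile.z[cols].to_numpy().ravel()
            for p in percentiles:
                row[f"p{p:g}"] = float(np.percentile(values, p))
        else:
            for p in percentiles:
                row[f"p{p:g}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["genotype", "day"]).reset_index(drop=True)
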