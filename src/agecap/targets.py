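"""Age-dependent transcription-factor target definition and binding-site folds.

A gene is an age-dependent target when the WT-vs-mutant contrast is
significant (adjusted p below ``alpha_target``, default 0.1) with a
consistent sign on both day 6 and day 7, and on both days the absolute log2
fold change exceeds its day-1 value.  The sign gives the up/down set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import hypergeom_tail
from .errors import ContractViolation


@dataclass(frozen=True)
class TargetCallConfig:
    alpha_target: float = 0.1
    required_days: tuple[int, int] = (6, 7)
    baseline_day: int = 1

    def validate(self) -> None:
        if not 0 < self.alpha_target < 1:
            raise ContractViolation("alpha_target must lie in (0, 1)")


@dataclass(frozen=True)
class TargetSets:
    """Genes up-/down-regulated by the factor with age (disjoint sets)."""

    up: frozenset[str]
    down: frozenset[str]


def define_age_targets(
    result_d1: pd.DataFrame,
    result_d6: pd.DataFrame,
    result_d7: pd.DataFrame,
    cfg: TargetCallConfig | None = None,
) -> TargetSets:
    """Call age-dependent targets from the genotype contrasts on days 1, 6, 7.

    All three results must share a gene universe.  Genes whose day-6 and
    day-7 fold changes disagree in sign are excluded.
    """
    cfg = cfg or TargetCallConfig()
    cfg.validate()
    for res, label in ((result_d1, "day-1"), (result_d6, "day-6"), (result_d7, "day-7")):
        if res is None:
            raise ContractViolation(f"missing {label} contrast result")
    if not (result_d1.index.equals(result_d6.index) and result_d1.index.equals(result_d7.index)):
        common = result_d1.index.intersection(result_d6.index).intersection(result_d7.index)
        if len(common) == 0:
            raise ContractViolation("contrast results share no genes")
        result_d1 = result_d1.loc[common]
        result_d6 = result_d6.loc[common]
        result_d7 = result_d7.loc[common]

    sig = (result_d6["p_adj"] < cfg.alpha_target) & (result_d7["p_adj"] < cfg.alpha_target)
    l1 = result_d1["log2_fc"].abs()
    exceeds_baseline = (result_d6["log2_fc"].abs() > l1) & (result_d7["log2_fc"].abs() > l1)
    up = sig & (result_d6["log2_fc"] > 0) & (result_d7["log2_fc"] > 0) & exceeds_baseline
    down = sig & (result_d6["log2_fc"] < 0) & (result_d7["log2_fc"] < 0) & exceeds_baseline
    return TargetSets(
        up=frozenset(result_d1.index[up]), down=frozenset(result_d1.index[down])
    )


def overlap_report(
    targets: TargetSets,
    class1: Iterable[str],
    class2: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Overlap of the age-dependent target sets with the two IIS class lists.

    For each pairing the report gives the intersection size, the share of the
    IIS list that is age-dependent, the share of the age-dependent set that is
    an IIS target, and a hypergeometric overlap p-value.
    """
    universe = frozenset(universe)
    if not universe:
        raise ContractViolation("overlap_report needs a non-empty universe")
    rows = []
    for target_name, target_set in (("up", targets.up), ("down", targets.down)):
        for iis_name, iis_list in (("class1", class1), ("class2", class2)):
            iis_set = frozenset(iis_list) & universe
            overlap = len(target_set & iis_set)
            rows.append(
                {
                    "target_set": target_name,
                    "iis_set": iis_name,
                    "n_targets": len(target_set),
                    "n_iis": len(iis_set),
                    "overlap": overlap,
                    "pct_of_iis": 100.0 * overlap / len(iis_set) if iis_set else np.nan,
                    "pct_of_targets": 100.0 * overlap / len(target_set)
                    if target_set
                    else np.nan,
                    "p_hypergeom": hypergeom_tail(
                        overlap, len(universe), len(iis_set), len(target_set)
                    ),
                }
            )
    return pd.DataFrame(rows)


def binding_site_fold(
    target: Iterable[str], background: Iterable[str], sites: pd.Series
) -> tuple[float, str]:
    """Ratio of binding-site fractions, phrased the way the field reports it.

    ``sites`` is a boolean Series indexed by gene; genes absent from it count
    as site-free.  Targets are removed from the background.  Returns
    ``(fold, orientation)`` where orientation is ``"enrichment"`` when the
    target fraction is at least the background fraction (fold = ratio) and
    ``"depletion"`` otherwise (fold = reciprocal ratio).
    """
    target = frozenset(target)
    background = frozenset(background) - target
    if not target or not background:
        raise ContractViolation("target and (target-free) background must be non-empty")

    def fraction(genes: frozenset[str]) -> float:
        values = sites.reindex(list(genes)).to_numpy()
        present = np.where(pd.isna(values), False, values).astype(bool)
        return float(present.sum()) / len(genes)

    f_target = fraction(target)
    f_background = fraction(background)
    if f_background == 0:
        if f_target == 0:
            raise ContractViolation("no binding sites in either set: fold undefined")
        raise ContractViolation("background site fraction is zero: fold undefined")
    ratio = f_target / f_background
    if ratio >= 1:
        return ratio, "enrichment"
    return 1.0 / ratio, "depletion"


def top_k_by_rank(ranked: Sequence[str], k: int) -> list[str]:
    """First ``k`` genes of an externally supplied ranking (ties by input order)."""
    if k < 0 or k > len(ranked):
        raise ContractViolation(f"k={k} outside the ranking length {len(ranked)}")
    return list(ranked[:k])


def assign_sites_from_bed(
    intervals: pd.DataFrame, gene_table: pd.DataFrame, upstream: int = 1000
) -> pd.Series:
    """Convention helper: map BED binding intervals to gene-level flags.

    ``intervals`` needs columns chrom, start, end (0-based half-open);
    ``gene_table`` needs gene_id, chrom, start, end, strand.  A gene carries a
    site when any interval overlaps its body or its ``upstream``-bp promoter
    window on the annotated strand.
    """
    flags = pd.Series(False, index=gene_table["gene_id"].tolist())
    by_chrom = {chrom: sub for chrom, sub in intervals.groupby("chrom")}
    for row in gene_table.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        if row.strand == "-":
            lo, hi = row.start, row.end + upstream
        else:
            lo, hi = max(0, row.start - upstream), row.end
        overlap = (sub["start"].to_numpy() < hi) & (sub["end"].to_numpy() > lo)
        if overlap.any():
            flags[row.gene_id] = True
    flags.index.name = "gene_id"
    return flags
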