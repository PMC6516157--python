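"""Per-day Venn-region taxonomy of DEGs over three contrasts.

For each day x >= 2 three DEG sets are formed: W (wild type day x vs day 1),
M (mutant day x vs day 1) and G (wild type vs mutant on day x).  With
w/m/g denoting membership, the regions are::

    A = w & g & !m      age change requiring DAF-16 (WT-only, genotype difference)
    B = w & m & g       age change in both, still genotype-different
    C = w & !m & !g     WT-only age change without a detectable genotype difference
    D = !w & m & g      mutant age change with a genotype difference
    E = w & m & !g      DAF-16-independent age change
    F = !w & m & !g     mutant-unique instability (the capacitor signature)
    G_only = !w & !m & g
    unchanged otherwise

This mapping is the unique assignment consistent with three constraints:
A+B+C+E is exactly the WT age-DEG set, A+C are the DEGs unique to the wild
type, and F the DEGs unique to the mutant.  A+B are the age- and
DAF-16-dependent genes; their share of all age-DEGs is
100 * (|A|+|B|) / (|A|+|B|+|C|+|E|).

Membership uses significance only (union of up and down); the per-contrast
direction is retained in the output but does not affect the region label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de_core import DEGSet
from .errors import ConsistencyError, ContractViolation

REGION_LABELS = ("A", "B", "C", "D", "E", "F", "G_only", "unchanged")


@dataclass(frozen=True)
class DayContrastTriple:
    """The three DEG sets that define the day-x Venn diagram."""

    day: int
    W: DEGSet
    M: DEGSet
    G: DEGSet
    universe: tuple[str, ...]


def _direction(degs: DEGSet, genes: Sequence[str]) -> np.ndarray:
    out = np.zeros(len(genes), dtype=int)
    up, down = degs.up, degs.down
    for i, gene in enumerate(genes):
        if gene in up:
            out[i] = 1
        elif gene in down:
            out[i] = -1
    return out


def classify_regions(triple: DayContrastTriple) -> pd.DataFrame:
    """Assign each universe gene its Venn region for one day.

    Returns a DataFrame indexed by gene with columns ``region`` and the
    per-contrast significant directions ``dir_w``, ``dir_m``, ``dir_g``
    (+1 up, -1 down, 0 not significant).
    """
    genes = list(triple.universe)
    universe = set(genes)
    for label, degs in (("W", triple.W), ("M", triple.M), ("G", triple.G)):
        stray = degs.genes - universe
        if stray:
            raise ConsistencyError(
                f"day {triple.day}: {label} contains genes outside the universe, "
                f"e.g. {sorted(stray)[:3]}"
            )

    dir_w = _direction(triple.W, genes)
    dir_m = _direction(triple.M, genes)
    dir_g = _direction(triple.G, genes)
    w = dir_w != 0
    m = dir_m != 0
    g = dir_g != 0

    region = np.select(
        [
            w & g & ~m,
            w & m & g,
            w & ~m & ~g,
            ~w & m & g,
            w & m & ~g,
            ~w & m & ~g,
            ~w & ~m & g,
        ],
        ["A", "B", "C", "D", "E", "F", "G_only"],
        default="unchanged",
    )
    return pd.DataFrame(
        {"region": region, "dir_w": dir_w, "dir_m": dir_m, "dir_g": dir_g},
        index=pd.Index(genes, name="gene_id"),
    )


def region_counts(assignments: Mapping[int, pd.DataFrame]) -> pd.DataFrame:
    """Per-day region tallies, the A+B share of age-DEGs, and novelty counts.

    ``ab_percentage`` is 100*(|A|+|B|)/(|A|+|B|+|C|+|E|), reported as NaN when
    the denominator is zero.  ``n_new`` / ``n_seen`` split each day's
    region-labelled genes by whether the gene held a region label on any
    earlier day (first-detection bookkeeping).
    """
    rows = []
    seen: set[str] = set()
    for day in sorted(assignments):
        assignment = assignments[day]
        tally = assignment["region"].value_counts()
        counts = {label: int(tally.get(label, 0)) for label in REGION_LABELS}
        ab = counts["A"] + counts["B"]
        denominator = ab + counts["C"] + counts["E"]
        labelled = set(assignment.index[assignment["region"] != "unchanged"])
        rows.append(
            {
                "day": day,
                **counts,
                "ab_count": ab,
                "ab_percentage": 100.0 * ab / denominator if denominator else np.nan,
                "n_new": len(labelled - seen),
                "n_seen": len(labelled & seen),
            }
        )
        seen |= labelled
    return pd.DataFrame(rows).set_index("day")


def fold_change_spread(lfc_w: pd.Series, lfc_m: pd.Series) -> dict[str, float]:
    """Spread of day-x-vs-day-1 log2 fold changes per genotype.

    Returns interdecile ranges (90th - 10th percentile) and variances for both
    genotypes plus the mutant/wild-type ratios; ``capacitor_index`` is the
    interdecile-range ratio, >1 when the mutant transcriptome drifts more.
    """
    lfc_w, lfc_m = lfc_w.align(lfc_m, join="inner")
    if len(lfc_w) < 10:
        raise ContractViolation("fold_change_spread needs at least 10 shared genes")
    w = lfc_w.to_numpy(dtype=float)
    m = lfc_m.to_numpy(dtype=float)
    idr_w = float(np.percentile(w, 90) - np.percentile(w, 10))
    idr_m = float(np.percentile(m, 90) - np.percentile(m, 10))
    var_w = float(np.var(w, ddof=1))
    var_m = float(np.var(m, ddof=1))
    return {
        "idr_wt": idr_w,
        "idr_mut": idr_m,
        "var_wt": var_w,
        "var_mut": var_m,
        "idr_ratio": idr_m / idr_w if idr_w else np.nan,
        "var_ratio": var_m / var_w if var_w else np.nan,
        "capacitor_index": idr_m / idr_w if idr_w else np.nan,
    }


def trend_correlation(lfc_age: pd.Series, lfc_genotype: pd.Series) -> float:
    """Spearman rho between the WT age response and the genotype contrast.

    Rising values across days indicate that the genotype's transcriptional
    output contributes increasingly to the age-associated remodeling.
    """
    lfc_age, lfc_genotype = lfc_age.align(lfc_genotype, join="inner")
    if len(lfc_age) < 10:
        raise ContractViolation("trend_correlation needs at least 10 shared genes")
    a = lfc_age.to_numpy(dtype=float)
    g = lfc_genotype.to_numpy(dtype=float)
    if np.all(a == a[0]) or np.all(g == g[0]):
        warnings.warn("constant fold-change vector: correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(a, g).statistic)
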