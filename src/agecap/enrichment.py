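"""Gene-set over-representation via the hypergeometric upper tail.

For a query of size n drawn from a universe of size N, a term with K members
and k of them in the query is scored by P(X >= k) under Hypergeom(N, K, n).
BH correction runs across all terms of one collection, and the reporting rule
keeps terms with adjusted p strictly below 0.05 and fold enrichment strictly
above 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .de_core import adjust_bh
from .errors import ContractViolation


def hypergeom_tail(k, N: int, K: int, n: int):
    """Upper-tail P(X >= k) for Hypergeom(N, K, n); ``k`` may be an array."""
    k_arr = np.asarray(k)
    if not (0 <= K <= N and 0 <= n <= N) or (k_arr < 0).any():
        raise ContractViolation(f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}")
    tail = np.where(k_arr == 0, 1.0, stats.hypergeom.sf(k_arr - 1, N, K, n))
    return float(tail) if np.isscalar(k) or k_arr.ndim == 0 else tail


@dataclass
class GeneSetCollection:
    """Term sets restricted to a background universe (empty terms dropped)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]
    dropped_terms: list[str] = field(default_factory=list)

    @classmethod
    def from_terms(
        cls,
        terms: dict[str, tuple[str, frozenset[str]]],
        universe: Iterable[str],
    ) -> "GeneSetCollection":
        universe = frozenset(universe)
        if not universe:
            raise ContractViolation("gene-set universe is empty")
        restricted: dict[str, tuple[str, frozenset[str]]] = {}
        dropped: list[str] = []
        for term_id, (name, genes) in terms.items():
            kept = genes & universe
            if kept:
                restricted[term_id] = (name, kept)
            else:
                dropped.append(term_id)
        return cls(terms=restricted, universe=universe, dropped_terms=dropped)


def hypergeom_enrich(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Score every term of a collection against a query gene set.

    Query genes outside the universe are dropped (and counted in the result's
    ``attrs["n_query_dropped"]``).  Rows are ordered by adjusted p.
    """
    query = frozenset(query)
    if not query:
        raise ContractViolation("empty query gene set")
    dropped = len(query - collection.universe)
    query &= collection.universe
    if not query:
        raise ContractViolation("no query genes inside the universe")

    N = len(collection.universe)
    n = len(query)
    rows = []
    for term_id, (name, genes) in collection.terms.items():
        K = len(genes)
        k = len(query & genes)
        fold = (k / n) / (K / N)
        rows.append(
            {
                "term_id": term_id,
                "name": name,
                "overlap": k,
                "term_size": K,
                "query_size": n,
                "universe_size": N,
                "fold_enrichment": fold,
                "p_raw": hypergeom_tail(k, N, K, n),
            }
        )
    result = pd.DataFrame(rows)
    result["p_adj"] = adjust_bh(result["p_raw"].to_numpy()) if len(result) else []
    result = result.sort_values(["p_adj", "p_raw", "term_id"]).reset_index(drop=True)
    result.attrs["n_query_dropped"] = dropped
    return result


def filter_enriched(
    results: pd.DataFrame, p_cut: float = 0.05, fold_cut: float = 2.0
) -> pd.DataFrame:
    """Reported terms: adjusted p strictly < p_cut and fold strictly > fold_cut."""
    keep = (results["p_adj"] < p_cut) & (results["fold_enrichment"] > fold_cut)
    return results[keep].reset_index(drop=True)
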