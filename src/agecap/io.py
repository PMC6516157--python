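"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts are a gene x sample TSV (first column ``gene_id``); the sample sheet is
a CSV with one row per sample; lifespans, truth tables, localization score
tables and site annotations are small TSVs; gene-set collections use the GMT
convention (term, description, then one gene per field).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AgecapError


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample count matrix; validates integer, non-negative counts."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise AgecapError(f"cannot read count matrix {path!r}: {exc}") from exc
    if df.index.has_duplicates:
        raise AgecapError(f"count matrix {path!r} has duplicated gene ids")
    if df.columns.has_duplicates:
        raise AgecapError(f"count matrix {path!r} has duplicated sample ids")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.isnan(values).any():
        raise AgecapError(f"count matrix {path!r} contains non-numeric entries")
    if (values < 0).any():
        raise AgecapError(f"count matrix {path!r} contains negative counts")
    if not np.array_equal(values, np.floor(values)):
        raise AgecapError(f"count matrix {path!r} contains non-integer counts")
    df.index.name = "gene_id"
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    try:
        sheet = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise AgecapError(f"cannot read sample sheet {path!r}: {exc}") from exc
    required = {"sample_id", "genotype", "day", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise AgecapError(f"sample sheet {path!r} lacks columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise AgecapError(f"sample sheet {path!r} has duplicated sample ids")
    if sheet.duplicated(["genotype", "day", "replicate"]).any():
        raise AgecapError(
            f"sample sheet {path!r} has duplicated (genotype, day, replicate) triples"
        )
    sheet["day"] = sheet["day"].astype(int)
    sheet["replicate"] = sheet["replicate"].astype(int)
    if "is_outlier_truth" in sheet.columns:
        sheet["is_outlier_truth"] = sheet["is_outlier_truth"].astype(bool)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sheet.to_csv(path, index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    if truth["gene_id"].duplicated().any():
        raise AgecapError(f"truth table {path!r} has duplicated gene ids")
    return truth


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_lifespans(path: str | os.PathLike) -> pd.DataFrame:
    """Lifespan records TSV: columns group, day_of_death, censored (0/1)."""
    records = pd.read_csv(path, sep="\t")
    required = {"group", "day_of_death", "censored"}
    missing = required - set(records.columns)
    if missing:
        raise AgecapError(f"lifespan table {path!r} lacks columns {sorted(missing)}")
    if (records["day_of_death"] <= 0).any():
        raise AgecapError(f"lifespan table {path!r} has non-positive event days")
    records["censored"] = records["censored"].astype(int)
    if not records["censored"].isin([0, 1]).all():
        raise AgecapError(f"lifespan table {path!r}: censored must be 0 or 1")
    return records


def write_lifespans(records: pd.DataFrame, path: str | os.PathLike) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene per line; blank lines and '#' comments ignored; order preserved."""
    genes: list[str] = []
    with open(path) as handle:
        for line in handle:
            name = line.strip()
            if name and not name.startswith("#"):
                genes.append(name)
    return genes


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file into {term_id: (description, gene set)}."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            terms[fields[0]] = (fields[1], frozenset(g for g in fields[2:] if g))
    return terms


def read_site_annotation(path: str | os.PathLike) -> pd.Series:
    """Two-column TSV (gene_id, 0/1) -> boolean Series indexed by gene."""
    table = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "has_site"],
                        comment="#")
    if table["gene_id"].duplicated().any():
        raise AgecapError(f"site annotation {path!r} has duplicated gene ids")
    return table.set_index("gene_id")["has_site"].astype(int).astype(bool)


def read_score_table(path: str | os.PathLike) -> pd.DataFrame:
    """Localization score table: rows = group/day, columns = score categories."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    values = table.to_numpy()
    if (values < 0).any() or not np.array_equal(values, np.floor(values)):
        raise AgecapError(f"score table {path!r} must hold non-negative integer counts")
    return table.astype(int)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_gene_set(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for gene in sorted(genes):
            handle.write(f"{gene}\n")
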