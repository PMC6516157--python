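"""End-to-end orchestration: simulate/load -> QC -> DE -> regions -> targets ->
trends -> enrichment, with a machine-readable manifest.

For a two-genotype, seven-day design the contrast plan is: each genotype's
day x vs day 1 for x >= 2 (6 + 6) plus wild type vs mutant on every day (7),
i.e. 19 contrasts.  QC filtering happens once, before all contrasts; genes
with fewer than ``min_total_count`` reads across retained samples are dropped
before DE to stabilize dispersion estimation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, de_core, io, qc, regions, targets, trends
from .de_core import ContrastSpec
from .errors import ConfigurationError
from .simdata import SimConfig, simulate_dataset

logger = logging.getLogger("agecap")


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds of one pipeline run."""

    out_dir: str = "agecap_run"
    counts_path: str | None = None
    sheet_path: str | None = None
    sim: SimConfig | None = field(default_factory=SimConfig)
    gmt_path: str | None = None
    alpha_deg: float = 0.05
    alpha_target: float = 0.1
    k: int = 6
    kmeans_seed: int = 0
    min_rho: float = 0.9
    min_total_count: int = 10

    def validate(self) -> None:
        for name, value in (("alpha_deg", self.alpha_deg), ("alpha_target", self.alpha_target)):
            if not 0 < value < 1:
                raise ConfigurationError(f"{name}: must lie in (0, 1)")
        if self.sim is None:
            for name, path in (("counts_path", self.counts_path), ("sheet_path", self.sheet_path)):
                if path is None:
                    raise ConfigurationError(f"{name}: required when no simulation block is given")
                if not Path(path).exists():
                    raise ConfigurationError(f"{name}: file {path!r} does not exist")
        if self.gmt_path is not None and not Path(self.gmt_path).exists():
            raise ConfigurationError(f"gmt_path: file {self.gmt_path!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim_block = raw.pop("sim", None)
        config = cls(**raw)
        config.sim = SimConfig(**sim_block) if isinstance(sim_block, dict) else (
            SimConfig() if sim_block in (True, "default") else None
        )
        return config


def plan_contrasts(sheet: pd.DataFrame) -> list[ContrastSpec]:
    """Build the genotype-age contrast plan a sheet supports.

    Age contrasts (day x vs day 1 within genotype, x >= 2) and per-day
    genotype contrasts are included only when both cells have >= 2 samples;
    missing cells are reported with a warning and skipped.
    """
    genotypes = sorted(sheet["genotype"].unique(), key=str)
    # wild type first when the conventional labels are present
    if set(genotypes) == {"WT", "MUT"}:
        genotypes = ["WT", "MUT"]
    days = sorted(sheet["day"].unique())
    cell_sizes = sheet.groupby(["genotype", "day"]).size()

    def usable(genotype: str, day: int) -> bool:
        return cell_sizes.get((genotype, day), 0) >= 2

    specs: list[ContrastSpec] = []
    skipped: list[str] = []
    for genotype in genotypes:
        for day in days:
            if day == days[0]:
                continue
            if usable(genotype, day) and usable(genotype, days[0]):
                specs.append(
                    ContrastSpec(
                        name=f"{genotype}_d{day}_vs_{genotype}_d{days[0]}",
                        group_a={"genotype": genotype, "day": day},
                        group_b={"genotype": genotype, "day": days[0]},
                    )
                )
            else:
                skipped.append(f"{genotype} day {day} vs day {days[0]}")
    if len(genotypes) == 2:
        a, b = genotypes
        for day in days:
            if usable(a, day) and usable(b, day):
                specs.append(
                    ContrastSpec(
                        name=f"{a}_d{day}_vs_{b}_d{day}",
                        group_a={"genotype": a, "day": day},
                        group_b={"genotype": b, "day": day},
                    )
                )
            else:
                skipped.append(f"{a} vs {b} day {day}")
    for item in skipped:
        warnings.warn(f"contrast skipped (cell below 2 samples): {item}", stacklevel=2)
    return specs


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value).__name__}")


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    config.validate()

    # ingest before any output is created so an I/O error leaves nothing behind
    if config.sim is not None:
        truth, counts, sheet = simulate_dataset(config.sim)
    else:
        truth = None
        counts = io.read_counts(config.counts_path)
        sheet = io.read_sample_sheet(config.sheet_path)
    gmt = io.read_gmt(config.gmt_path) if config.gmt_path else None

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if truth is not None:
        io.write_truth(truth, out / "truth.tsv")
        io.write_counts(counts, out / "counts.tsv")
        io.write_sample_sheet(sheet, out / "sample_sheet.csv")

    # --- QC -------------------------------------------------------------
    logger.info("QC: Spearman screen over %d samples", counts.shape[1])
    sf_all = de_core.estimate_size_factors(counts)
    corr = qc.spearman_matrix(counts, sf_all)
    report = qc.flag_outliers(corr, sheet, min_rho=config.min_rho)
    io.write_table(corr, out / "sample_correlation.tsv")
    io.write_table(report.median_rho.to_frame(), out / "qc_median_rho.tsv")
    (out / "qc_flagged_samples.txt").write_text("".join(f"{s}\n" for s in report.flagged))

    retained = [s for s in counts.columns if s not in set(report.flagged)]
    counts = counts[retained]
    sheet = sheet[sheet["sample_id"].isin(retained)].reset_index(drop=True)

    # --- expression filter + normalization ------------------------------
    keep_genes = counts.sum(axis=1) >= config.min_total_count
    counts = counts[keep_genes]
    logger.info("retained %d samples, %d genes", counts.shape[1], counts.shape[0])
    size_factors = de_core.estimate_size_factors(counts)
    cell_labels = sheet.set_index("sample_id").apply(
        lambda row: f"{row['genotype']}_d{row['day']}", axis=1
    )
    alphas = de_core.estimate_dispersions(counts, size_factors, cell_labels)
    norm_counts = counts / size_factors

    # --- differential expression ---------------------------------------
    specs = plan_contrasts(sheet)
    results: dict[str, pd.DataFrame] = {}
    deg_sets: dict[str, de_core.DEGSet] = {}
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    for spec in specs:
        result = de_core.wald_contrast(counts, sheet, spec, size_factors, alphas)
        results[spec.name] = result
        deg_sets[spec.name] = de_core.call_degs(result, config.alpha_deg)
        io.write_table(result, de_dir / f"{spec.name}.tsv")

    genotypes = ["WT", "MUT"] if set(sheet["genotype"]) == {"WT", "MUT"} else sorted(
        sheet["genotype"].unique(), key=str
    )
    days = sorted(sheet["day"].unique())
    wt, mut = genotypes if len(genotypes) == 2 else (genotypes[0], None)

    # --- region taxonomy -------------------------------------------------
    assignments: dict[int, pd.DataFrame] = {}
    spread_rows = []
    trend_rows = []
    universe = tuple(counts.index)
    for day in days[1:]:
        names = {
            "W": f"{wt}_d{day}_vs_{wt}_d{days[0]}",
            "M": f"{mut}_d{day}_vs_{mut}_d{days[0]}",
            "G": f"{wt}_d{day}_vs_{mut}_d{day}",
        }
        if not all(name in deg_sets for name in names.values()):
            continue
        triple = regions.DayContrastTriple(
            day=day,
            W=deg_sets[names["W"]],
            M=deg_sets[names["M"]],
            G=deg_sets[names["G"]],
            universe=universe,
        )
        assignment = regions.classify_regions(triple)
        assignments[day] = assignment
        io.write_table(assignment, out / f"regions_day{day}.tsv")
        spread_rows.append(
            {
                "day": day,
                **regions.fold_change_spread(
                    results[names["W"]]["log2_fc"], results[names["M"]]["log2_fc"]
                ),
            }
        )
        trend_rows.append(
            {
                "day": day,
                "spearman_rho": regions.trend_correlation(
                    results[names["W"]]["log2_fc"], results[names["G"]]["log2_fc"]
                ),
            }
        )
    if assignments:
        io.write_table(regions.region_counts(assignments), out / "region_counts.tsv")
        io.write_table(pd.DataFrame(spread_rows).set_index("day"), out / "fold_change_spread.tsv")
        io.write_table(pd.DataFrame(trend_rows).set_index("day"), out / "trend_correlation.tsv")

    # --- age-dependent targets ------------------------------------------
    target_sets = None
    geno_names = {d: f"{wt}_d{d}_vs_{mut}_d{d}" for d in (days[0], 6, 7)}
    if mut is not None and all(name in results for name in geno_names.values()):
        target_sets = targets.define_age_targets(
            results[geno_names[days[0]]],
            results[geno_names[6]],
            results[geno_names[7]],
            targets.TargetCallConfig(alpha_target=config.alpha_target),
        )
        io.write_gene_set(target_sets.up, out / "targets_up.txt")
        io.write_gene_set(target_sets.down, out / "targets_down.txt")

    # --- temporal trends -------------------------------------------------
    cluster_info = None
    if target_sets is not None and len(target_sets.up | target_sets.down) >= config.k:
        profile = trends.zscore_profiles(norm_counts, sorted(target_sets.up | target_sets.down))
        clusters = trends.kmeans_profiles(
            profile, k=config.k, max_iter=1000, seed=config.kmeans_seed
        )
        bands = trends.percentile_bands(profile, sheet)
        io.write_table(clusters.labels.to_frame(), out / "cluster_labels.tsv")
        io.write_table(clusters.centroids, out / "cluster_centroids.tsv")
        io.write_table(bands, out / "percentile_bands.tsv", index=False)
        cluster_info = {"k": config.k, "wcss": clusters.wcss, "iterations": clusters.iterations}

    # --- enrichment -------------------------------------------------------
    enrichment_files = []
    if gmt and target_sets is not None:
        from .enrichment import GeneSetCollection, hypergeom_enrich

        collection = GeneSetCollection.from_terms(gmt, universe)
        for label, query in (("up", target_sets.up), ("down", target_sets.down)):
            if query:
                table = hypergeom_enrich(query, collection)
                io.write_table(table, out / f"enrichment_targets_{label}.tsv", index=False)
                enrichment_files.append(f"enrichment_targets_{label}.tsv")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "agecap_version": __version__,
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("sim",)
            },
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
        },
        "n_samples_retained": counts.shape[1],
        "n_genes_retained": counts.shape[0],
        "flagged_samples": sorted(report.flagged),
        "low_confidence_cells": [list(cell) for cell in report.low_confidence_cells],
        "contrasts": [spec.name for spec in specs],
        "n_contrasts": len(specs),
        "region_days": sorted(assignments),
        "n_region_tables": len(assignments),
        "target_sets": None
        if target_sets is None
        else {"n_up": len(target_sets.up), "n_down": len(target_sets.down)},
        "clustering": cluster_info,
        "enrichment_outputs": enrichment_files,
        "outputs": {},
    }
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
    return manifest
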