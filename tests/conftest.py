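import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from agecap import de_core
from agecap.pipeline import plan_contrasts
from agecap.simdata import SimConfig, simulate_dataset

settings.register_profile(
    "agecap",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("agecap")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic experiment: (config, truth indexed by gene, counts, sheet)."""
    config = SimConfig(seed=7)
    truth, counts, sheet = simulate_dataset(config)
    return config, truth.set_index("gene_id"), counts, sheet


def run_de(counts: pd.DataFrame, sheet: pd.DataFrame, min_total: int = 10):
    """Filter, normalize and run every planned contrast; returns (results, counts)."""
    counts = counts[counts.sum(axis=1) >= min_total]
    size_factors = de_core.estimate_size_factors(counts)
    cells = sheet.set_index("sample_id").apply(
        lambda row: f"{row['genotype']}_d{row['day']}", axis=1
    )
    alphas = de_core.estimate_dispersions(counts, size_factors, cells)
    results = {
        spec.name: de_core.wald_contrast(counts, sheet, spec, size_factors, alphas)
        for spec in plan_contrasts(sheet)
    }
    return results, counts


@pytest.fixture(scope="session")
def default_de(default_dataset):
    """DE results for every contrast of the default synthetic experiment."""
    _, truth, counts, sheet = default_dataset
    results, filtered = run_de(counts, sheet)
    return truth.loc[filtered.index], filtered, sheet, results


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
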