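"""Synthetic two-genotype aging-transcriptome data with planted structure.

The generator emulates the study design the downstream stages assume: two
genotypes (wild type and a daf-16 null), adult days 1-7, three biological
replicates, negative-binomial counts with library-size factors and a
mean-dispersion trend.  Gene archetypes plant the signals the analysis is
meant to recover:

``stable``
    constant expression in both genotypes.
``age_up`` / ``age_down``
    a genotype-independent log-linear age trend.
``daf16_target_up`` / ``daf16_target_down``
    a DAF-16-driven induction (or repression) present only in the wild type,
    switched on at ``target_onset_day`` and at full strength by
    ``target_full_day``; the mutant lacks it, so the WT-vs-MUT log2 fold
    change of an up-target is positive on late days.
``capacitor``
    genes whose age response is destabilized in the mutant: the wild type
    drifts linearly to amplitude A by the last day, whereas the mutant moves
    ``capacitor_gain`` times faster and saturates slightly above A
    (``capacitor_overshoot``).  Early in adulthood the mutant has already
    changed while the wild type has barely moved; by the last day the two
    genotypes nearly coincide.  This saturating shape is what lets the
    mutant's day-2 age contrast dwarf the wild type's while keeping the late
    WT-vs-MUT contrasts small, mirroring a transcriptome-stabilizing factor.
``class1_like`` / ``class2_like``
    insulin-signaling-class analogues: a WT-only late induction versus a
    genotype-independent decline.

Counts follow NB(mean = s_j * base_mean * 2**signal, variance = mu + alpha*mu^2)
with per-gene dispersion alpha = a1/base_mean + a0.  Optional outlier samples
have their counts permuted across genes, which destroys the rank correlation
the QC stage screens for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError

ARCHETYPES = (
    "stable",
    "age_up",
    "age_down",
    "daf16_target_up",
    "daf16_target_down",
    "capacitor",
    "class1_like",
    "class2_like",
)

#: Default planted composition: 50% stable, 20% capacitor, 16% DAF-16 targets
#: (10% up / 6% down), 10% age-trend genes, 2% + 2% insulin-class analogues.
DEFAULT_FRACTIONS: dict[str, float] = {
    "age_up": 0.05,
    "age_down": 0.05,
    "daf16_target_up": 0.10,
    "daf16_target_down": 0.06,
    "capacitor": 0.20,
    "class1_like": 0.02,
    "class2_like": 0.02,
}


@dataclass
class SimConfig:
    """Design and effect-size parameters of a synthetic experiment."""

    n_genes: int = 5000
    days: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    n_reps: int = 3
    genotypes: tuple[str, str] = ("WT", "MUT")
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    # log-normal baseline expression (natural-log scale)
    base_mean_log_mu: float = 5.0
    base_mean_log_sigma: float = 1.2
    # dispersion trend alpha(mu) = a1/mu + a0
    dispersion_a0: float = 0.01
    dispersion_a1: float = 1.5
    # planted DAF-16 target effect
    target_lfc: float = 2.0
    target_onset_day: int = 4
    target_full_day: int = 6
    # genotype-independent age trends (log2/day magnitudes)
    age_slope_min: float = 0.2
    age_slope_max: float = 0.6
    # capacitor genes: WT reaches amplitude A (log2) on the last day;
    # MUT moves capacitor_gain x faster and saturates at overshoot * A
    capacitor_lfc_min: float = 1.2
    capacitor_lfc_max: float = 1.8
    capacitor_gain: float = 3.0
    capacitor_overshoot: float = 1.15
    class1_lfc: float = 1.5
    class2_slope: float = -0.3
    libsize_sigma: float = 0.15
    n_outliers: int = 0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.days) * self.n_reps

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes: must be >= 1")
        days = tuple(self.days)
        if not days or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError("days: must be strictly increasing")
        if days[0] != 1:
            raise ConfigurationError("days: day 1 must be present")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps: must be >= 2")
        if len(set(self.genotypes)) != 2:
            raise ConfigurationError("genotypes: need two distinct labels")
        for name, frac in self.archetype_fractions.items():
            if name not in ARCHETYPES or name == "stable":
                raise ConfigurationError(f"archetype_fractions: unknown archetype {name!r}")
            if frac < 0:
                raise ConfigurationError(f"archetype_fractions[{name}]: must be >= 0")
        if sum(self.archetype_fractions.values()) > 1 + 1e-9:
            raise ConfigurationError("archetype_fractions: fractions sum to > 1")
        if self.dispersion_a0 <= 0 or self.dispersion_a1 <= 0:
            raise ConfigurationError("dispersion_a0/dispersion_a1: must be > 0")
        if self.capacitor_gain < 1:
            raise ConfigurationError("capacitor_gain: must be >= 1")
        if self.capacitor_overshoot < 1:
            raise ConfigurationError("capacitor_overshoot: must be >= 1")
        if not (days[0] <= self.target_onset_day <= self.target_full_day <= days[-1]):
            raise ConfigurationError(
                "target_onset_day/target_full_day: need day1 <= onset <= full <= last day"
            )
        if self.libsize_sigma < 0:
            raise ConfigurationError("libsize_sigma: must be >= 0")
        if not 0 <= self.n_outliers <= self.n_samples:
            raise ConfigurationError("n_outliers: must be within the sample count")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw the per-gene ground truth table for a configuration.

    Archetype labels are assigned by stratified allocation (rounded
    fraction x n_genes per archetype, remainder stable) onto a seeded random
    permutation of genes, so the archetype counts are deterministic and the
    placement is random.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_genes

    labels = np.array(["stable"] * n, dtype=object)
    order = rng.permutation(n)
    cursor = 0
    for name in ARCHETYPES:
        if name == "stable":
            continue
        frac = config.archetype_fractions.get(name, 0.0)
        k = int(round(frac * n))
        k = min(k, n - cursor)
        labels[order[cursor:cursor + k]] = name
        cursor += k

    base_mean = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma, n)
    dispersion = config.dispersion_a1 / base_mean + config.dispersion_a0

    age_slope = np.zeros(n)
    target_lfc = np.zeros(n)
    span = max(config.days) - 1

    for name, idx in (
        ("age_up", labels == "age_up"),
        ("age_down", labels == "age_down"),
    ):
        k = int(idx.sum())
        mag = rng.uniform(config.age_slope_min, config.age_slope_max, k)
        age_slope[idx] = mag if name == "age_up" else -mag

    cap = labels == "capacitor"
    k = int(cap.sum())
    amp = rng.uniform(config.capacitor_lfc_min, config.capacitor_lfc_max, k)
    sign = rng.choice([-1.0, 1.0], k)
    age_slope[cap] = sign * amp / max(span, 1)

    age_slope[labels == "class2_like"] = config.class2_slope
    target_lfc[labels == "daf16_target_up"] = config.target_lfc
    target_lfc[labels == "daf16_target_down"] = -config.target_lfc
    target_lfc[labels == "class1_like"] = config.class1_lfc

    width = len(str(n - 1))
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in range(n)],
            "archetype": labels,
            "base_mean": base_mean,
            "age_slope": age_slope,
            "target_lfc": target_lfc,
            "dispersion": dispersion,
        }
    )


def _target_ramp(day: np.ndarray | float, config: SimConfig) -> np.ndarray | float:
    """0 before onset, linear to 1 between onset and full-strength day."""
    num = np.asarray(day, dtype=float) - config.target_onset_day + 1
    den = config.target_full_day - config.target_onset_day + 1
    return np.clip(num / den, 0.0, 1.0)


def log2_signal(truth: pd.DataFrame, genotype: str, day: int, config: SimConfig) -> np.ndarray:
    """Planted log2 deviation from baseline for every gene in one sample cell."""
    is_wt = genotype == config.genotypes[0]
    arch = truth["archetype"].to_numpy()
    slope = truth["age_slope"].to_numpy()
    tlfc = truth["target_lfc"].to_numpy()
    d = day - 1
    span = max(config.days) - 1

    signal = slope * d  # genotype-shared trend (age_*, class2_like, WT capacitor)

    cap = arch == "capacitor"
    if not is_wt and cap.any():
        amp = np.abs(slope[cap]) * max(span, 1)
        mut = np.sign(slope[cap]) * np.minimum(
            config.capacitor_overshoot * amp,
            config.capacitor_gain * np.abs(slope[cap]) * d,
        )
        signal = signal.copy()
        signal[cap] = mut

    if is_wt:
        targeted = np.isin(arch, ("daf16_target_up", "daf16_target_down", "class1_like"))
        if targeted.any():
            signal = signal + np.where(targeted, tlfc * _target_ramp(day, config), 0.0)
    return signal


def simulate_counts(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the count matrix and sample sheet implied by a truth table.

    Returns ``(counts, sheet)``: counts is a gene x sample integer DataFrame,
    sheet has columns sample_id, genotype, day, replicate, is_outlier_truth.
    The true size factors are stored in ``counts.attrs["size_factors"]``.
    """
    config.validate()
    if len(truth) != config.n_genes:
        raise ConsistencyError(
            f"truth table has {len(truth)} genes but config.n_genes={config.n_genes}"
        )
    rng = _rng(config, 1)

    rows = []
    for genotype in config.genotypes:
        for day in config.days:
            for rep in range(1, config.n_reps + 1):
                rows.append((f"{genotype}_d{day}_r{rep}", genotype, day, rep))
    sheet = pd.DataFrame(rows, columns=["sample_id", "genotype", "day", "replicate"])

    n_samp = len(sheet)
    if config.libsize_sigma > 0:
        size_factors = rng.lognormal(0.0, config.libsize_sigma, n_samp)
        size_factors /= np.exp(np.mean(np.log(size_factors)))
    else:
        size_factors = np.ones(n_samp)

    base = truth["base_mean"].to_numpy()
    alpha = truth["dispersion"].to_numpy()

    mu = np.empty((config.n_genes, n_samp))
    for j, (genotype, day) in enumerate(zip(sheet["genotype"], sheet["day"])):
        mu[:, j] = size_factors[j] * base * np.exp2(log2_signal(truth, genotype, day, config))

    # gamma-Poisson mixture: NB with variance mu + alpha * mu^2
    lam = rng.gamma(shape=1.0 / alpha[:, None], scale=alpha[:, None] * mu)
    counts = rng.poisson(lam)

    outlier = np.zeros(n_samp, dtype=bool)
    if config.n_outliers:
        chosen = rng.choice(n_samp, size=config.n_outliers, replace=False)
        for j in chosen:
            counts[:, j] = counts[rng.permutation(config.n_genes), j]
        outlier[chosen] = True
    sheet["is_outlier_truth"] = outlier

    counts_df = pd.DataFrame(
        counts, index=pd.Index(truth["gene_id"], name="gene_id"),
        columns=sheet["sample_id"].tolist(),
    )
    counts_df.attrs["size_factors"] = pd.Series(size_factors, index=counts_df.columns)
    return counts_df, sheet


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: returns (truth, counts, sheet)."""
    truth = generate_truth(config)
    counts, sheet = simulate_counts(truth, config)
    return truth, counts, sheet


@dataclass
class LifespanGroup:
    """Parametric lifespan distribution for one assay arm.

    Deaths are drawn from a Weibull with the given shape (steepness of the
    mortality curve; ~4 gives the sigmoidal survival typical of worm assays)
    and scale chosen so the continuous mean equals ``mean_lifespan`` days,
    then discretized by ceiling to whole days.
    """

    n: int
    mean_lifespan: float
    shape: float = 4.0
    censor_frac: float = 0.0

    def validate(self, label: str) -> None:
        if self.mean_lifespan <= 0:
            raise ConfigurationError(f"{label}.mean_lifespan: must be > 0")
        if self.n < 1:
            raise ConfigurationError(f"{label}.n: must be >= 1")
        if self.shape <= 0:
            raise ConfigurationError(f"{label}.shape: must be > 0")
        if not 0 <= self.censor_frac < 1:
            raise ConfigurationError(f"{label}.censor_frac: must be in [0, 1)")


def simulate_lifespans(group_params: dict[str, LifespanGroup], seed: int) -> pd.DataFrame:
    """Draw lifespan records: columns group, day_of_death, censored (0/1).

    A censored animal is assigned a uniformly drawn observation day no later
    than its (unobserved) death day.
    """
    for label, params in group_params.items():
        params.validate(label)
    rng = np.random.default_rng(seed)
    frames = []
    for label, params in group_params.items():
        scale = params.mean_lifespan / math.gamma(1 + 1 / params.shape)
        t = scale * rng.weibull(params.shape, params.n)
        days = np.maximum(1, np.ceil(t)).astype(int)
        censored = rng.random(params.n) < params.censor_frac
        obs = days.copy()
        if censored.any():
            obs[censored] = rng.integers(1, days[censored] + 1)
        frames.append(
            pd.DataFrame({"group": label, "day_of_death": obs, "censored": censored.astype(int)})
        )
    return pd.concat(frames, ignore_index=True)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of ``config`` with a different seed (fractions dict deep-copied)."""
    return replace(config, archetype_fractions=dict(config.archetype_fractions), seed=seed)
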