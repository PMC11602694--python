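"""Synthetic data generation for the common-garden heat-stress analysis.

Generates the four inputs the pipeline consumes — daily necrosis
trajectories from repeated common-garden experiments, diploid
microsatellite genotypes, a multi-year daily seawater-temperature series,
and an in-situ field survey of necrosis — with the statistical structure
the downstream analysis assumes:

* necrosis variance dominated by the year (environmental) component with
  per-colony random baselines,
* population differentiation at a controlled expected F_ST
  (Balding–Nichols drift model),
* a sinusoidal seasonal temperature cycle with AR(1) noise and injected
  marine-heatwave / heat-spike windows recorded as ground truth,
* zero-inflated, heavy-tailed survey necrosis distributions.

Every generator derives its own child seed deterministically from the one
seed in :class:`SimConfig`, so fixtures are reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_POPULATIONS = ("PotaDelLlop", "LaVaca", "Tascons")
DEFAULT_YEARS = (2015, 2016, 2017)

# Child-seed offsets: one fixed stream per generator.
_STREAM_NECROSIS = 0
_STREAM_GENOTYPES = 1
_STREAM_TEMPERATURE = 2
_STREAM_SURVEY = 3


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study design: 3 populations of 30 tagged
    colonies assayed in 3 consecutive yearly common gardens of 28 days,
    a strongly year-dominated necrosis response (the third year lethal),
    14 microsatellite loci at low differentiation, and a 14-year daily
    temperature series at coastal Mediterranean 15 m conditions.
    """

    seed: int = 0
    # --- necrosis panel ---
    n_populations: int = 3
    n_colonies_per_pop: int = 30
    years: Sequence[int] = DEFAULT_YEARS
    n_days: int = 28
    year_effects: Sequence[float] = (0.0, 0.5, 6.0)
    sigma_individual: float = 0.25
    sigma_population: float = 0.0
    sigma_residual: float = 0.5
    missing_year_fraction: float = 0.13
    latent_intercept: float = -4.8
    day_slope: float = 0.15
    # --- genotypes ---
    n_loci: int = 14
    alleles_per_locus: tuple[int, int] = (4, 10)
    theta_target: float = 0.025
    missing_call_fraction: float = 0.0
    # --- temperature ---
    start_year: int = 2004
    n_temp_years: int = 14
    temp_baseline: tuple[float, float, float] = (17.5, 4.5, 215.0)
    ar1_phi: float = 0.8
    ar1_sigma: float = 0.5
    injected_events: Sequence[tuple[str, int, float]] = ()
    # --- field survey ---
    survey_n_per_pop: int = 20
    survey_mixture: dict | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_individual", "sigma_population", "sigma_residual",
                     "ar1_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_days < 10:
            raise ValueError("n_days must be >= 10 (fitness PCA trims days 1-9)")
        if not 0.0 <= self.theta_target < 1.0:
            raise ValueError("theta_target must be in [0, 1)")
        if self.alleles_per_locus[0] < 2:
            raise ValueError("alleles_per_locus must allow >= 2 alleles")
        if len(self.year_effects) != len(self.years):
            raise ValueError("year_effects must match years in length")
        if not 0.0 <= self.missing_year_fraction <= 1.0:
            raise ValueError("missing_year_fraction must be a probability")
        for ev in self.injected_events:
            if ev[1] < 1:
                raise ValueError("injected event durations must be >= 1 day")

    def populations(self) -> list[str]:
        if self.n_populations <= len(DEFAULT_POPULATIONS):
            return list(DEFAULT_POPULATIONS[: self.n_populations])
        return [f"Pop{i + 1}" for i in range(self.n_populations)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(stream + 1)[stream]
        )


@dataclass
class NecrosisSim:
    panel: pd.DataFrame  # colony_id, population, year, day, necrosis_pct
    truth: dict


@dataclass
class GenotypeMatrix:
    """Diploid microsatellite calls.

    ``calls`` has shape (n_individuals, n_loci, 2) holding positive
    integer allele codes, with 0/0 marking a missing call (both alleles
    missing or both present).
    """

    ids: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValueError("calls must have shape (n, n_loci, 2)")
        half_missing = (calls == 0).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("half-missing diploid calls are not allowed")
        self.calls = calls.astype(np.int64)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, n_loci): call present."""
        return self.calls[:, :, 0] > 0


@dataclass
class GenotypeSim:
    matrix: GenotypeMatrix
    truth: dict


@dataclass
class TemperatureSim:
    series: pd.DataFrame  # date, temp_c
    truth: dict


@dataclass
class SurveySim:
    table: pd.DataFrame  # colony_id, population, necrosis_pct
    truth: dict


# ---------------------------------------------------------------------------
# Necrosis panel
# ---------------------------------------------------------------------------

def _necrosis_from_latent(latent: np.ndarray) -> np.ndarray:
    """Map a latent propensity path to the observed 5%-grid necrosis scale.

    The running maximum guarantees monotone non-decreasing trajectories;
    rounding the logistic to the 5% grid makes 100% absorbing.
    """
    path = np.maximum.accumulate(latent, axis=-1)
    frac = 1.0 / (1.0 + np.exp(-path))
    return 5.0 * np.round(100.0 * np.clip(frac, 0.0, 1.0) / 5.0)


def simulate_necrosis_panel(config: SimConfig) -> NecrosisSim:
    """Simulate daily % tissue necrosis per colony × year.

    Latent model: L(i,y,d) = mu + beta_year(y) + pi_pop + u_i + s*d + eps,
    pushed through a running max, a logistic link and 5% rounding.  A
    fraction of colonies misses exactly one year (completely at random),
    so every colony is retained under the >= 2-years inclusion rule.
    """
    rng = config.rng(_STREAM_NECROSIS)
    pops = config.populations()
    years = list(config.years)
    days = np.arange(1, config.n_days + 1)

    pop_effects = rng.normal(0.0, config.sigma_population, len(pops))
    records = []
    colony_effects: dict[str, float] = {}
    dropped: dict[str, int] = {}
    for p_idx, pop in enumerate(pops):
        for c in range(config.n_colonies_per_pop):
            cid = f"{pop}-{c + 1:02d}"
            u = rng.normal(0.0, config.sigma_individual)
            colony_effects[cid] = u
            miss_year = -1
            if len(years) > 2 and rng.random() < config.missing_year_fraction:
                miss_year = int(rng.integers(len(years)))
                dropped[cid] = years[miss_year]
            for y_idx, year in enumerate(years):
                if y_idx == miss_year:
                    continue
                eps = rng.normal(0.0, config.sigma_residual, len(days))
                latent = (config.latent_intercept
                          + config.year_effects[y_idx]
                          + pop_effects[p_idx]
                          + u
                          + config.day_slope * days
                          + eps)
                nec = _necrosis_from_latent(latent)
                records.extend(
                    (cid, pop, year, int(d), float(v))
                    for d, v in zip(days, nec)
                )
    panel = pd.DataFrame(
        records, columns=["colony_id", "population", "year", "day", "necrosis_pct"]
    )
    truth = {
        "year_effects": dict(zip(years, map(float, config.year_effects))),
        "population_effects": dict(zip(pops, map(float, pop_effects))),
        "colony_effects": colony_effects,
        "dropped_colony_years": dropped,
        "sigma_individual": config.sigma_individual,
        "sigma_residual": config.sigma_residual,
    }
    return NecrosisSim(panel, truth)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypeSim:
    """Simulate diploid microsatellite genotypes under drift.

    Per-population allele frequencies follow a Balding–Nichols model:
    ancestral frequencies p (symmetric Dirichlet across alleles), then
    population frequencies ~ Dirichlet(p * (1 - theta) / theta).  theta
    equals the expected Weir–Cockerham F_ST, giving a closed-form
    calibration target.  Genotypes are drawn under within-population
    Hardy–Weinberg proportions.
    """
    rng = config.rng(_STREAM_GENOTYPES)
    pops = config.populations()
    n = config.n_colonies_per_pop
    theta = config.theta_target

    ids: list[str] = []
    pop_labels: list[str] = []
    for pop in pops:
        for c in range(n):
            ids.append(f"{pop}-{c + 1:02d}")
            pop_labels.append(pop)

    loci = [f"Loc{l + 1:02d}" for l in range(config.n_loci)]
    calls = np.zeros((len(ids), config.n_loci, 2), dtype=np.int64)
    ancestral: dict[str, list[float]] = {}
    lo, hi = config.alleles_per_locus
    for l in range(config.n_loci):
        k = int(rng.integers(lo, hi + 1))
        p_anc = rng.dirichlet(np.ones(k))
        ancestral[loci[l]] = [float(x) for x in p_anc]
        row = 0
        for _pop in pops:
            if theta == 0.0:
                p_pop = p_anc
            else:
                p_pop = rng.dirichlet(p_anc * (1.0 - theta) / theta)
            draws = rng.choice(k, size=(n, 2), p=p_pop) + 1  # codes 1..k
            calls[row:row + n, l, :] = draws
            row += n
    if config.missing_call_fraction > 0:
        miss = rng.random((len(ids), config.n_loci)) < config.missing_call_fraction
        calls[miss] = 0
    matrix = GenotypeMatrix(ids, pop_labels, loci, calls)
    truth = {"theta_target": theta, "ancestral_freqs": ancestral}
    return GenotypeSim(matrix, truth)


# ---------------------------------------------------------------------------
# Temperature series
# ---------------------------------------------------------------------------

def simulate_temperature_series(config: SimConfig) -> TemperatureSim:
    """Simulate a daily mean temperature series at fixed depth.

    Sinusoidal seasonal cycle + AR(1) noise + a rectangular additive
    anomaly for each injected event.  Event exceedance is expressed in
    folds of the stationary (iT90 − mean) threshold width
    1.2816 · σ / sqrt(1 − φ²), so an injected fold f sits at detection
    fold ≈ f.  With ``ar1_sigma = 0`` that width is zero and the
    exceedance is interpreted in °C instead (noise-free series are used
    for exact-recovery checks, where only the boundaries matter).  The
    exact windows are recorded as ground truth.
    """
    if config.n_temp_years < 2:
        raise ValueError("need >= 2 years of temperature for a climatology")
    rng = config.rng(_STREAM_TEMPERATURE)
    dates = pd.date_range(
        f"{config.start_year}-01-01",
        f"{config.start_year + config.n_temp_years - 1}-12-31",
        freq="D",
    )
    mean_c, amp_c, peak_doy = config.temp_baseline
    doy = dates.dayofyear.to_numpy().astype(float)
    seasonal = mean_c + amp_c * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)

    noise = np.zeros(len(dates))
    if config.ar1_sigma > 0:
        innov = rng.normal(0.0, config.ar1_sigma, len(dates))
        stationary_sd = config.ar1_sigma / np.sqrt(1 - config.ar1_phi ** 2)
        noise[0] = rng.normal(0.0, stationary_sd)
        for t in range(1, len(dates)):
            noise[t] = config.ar1_phi * noise[t - 1] + innov[t]
        delta90 = 1.2816 * stationary_sd
    else:
        delta90 = 1.0  # noise-free: event exceedance given directly in degC

    temp = seasonal + noise
    events = []
    occupied = np.zeros(len(dates), dtype=bool)
    for start, duration, fold in config.injected_events:
        start_ts = pd.Timestamp(start)
        i0 = dates.searchsorted(start_ts)
        if i0 >= len(dates) or dates[i0] != start_ts:
            raise ValueError(f"injected event start {start} outside series")
        i1 = i0 + int(duration)
        if i1 > len(dates):
            raise ValueError(f"injected event at {start} runs past the series")
        if occupied[i0:i1].any():
            raise ValueError("injected events overlap")
        occupied[i0:i1] = True
        temp[i0:i1] += fold * delta90
        events.append({
            "start": str(dates[i0].date()),
            "end": str(dates[i1 - 1].date()),
            "duration": int(duration),
            "fold": float(fold),
        })
    series = pd.DataFrame({"date": dates, "temp_c": temp})
    truth = {"injected_events": events, "threshold_width": float(delta90)}
    return TemperatureSim(series, truth)


# ---------------------------------------------------------------------------
# Field survey
# ---------------------------------------------------------------------------

#: zero-inflation probability and Beta(a, b) shape of the non-zero
#: necrosis fraction, per population: two heavily-impacted populations
#: with heavy right tails (SD > mean) and one lightly-impacted one.
_DEFAULT_SURVEY_MIXTURE = {
    "PotaDelLlop": (0.18, 0.45, 0.75),
    "Tascons": (0.23, 0.50, 0.80),
    "LaVaca": (0.29, 1.30, 12.0),
}


def simulate_field_survey(config: SimConfig) -> SurveySim:
    """Simulate an in-situ necrosis survey.

    Per-colony % necrosis is drawn from a population-specific
    zero-inflated Beta mixture and rounded to the 5% visual grid.
    """
    rng = config.rng(_STREAM_SURVEY)
    pops = config.populations()
    mixture = dict(_DEFAULT_SURVEY_MIXTURE)
    if config.survey_mixture:
        mixture.update(config.survey_mixture)
    records = []
    for pop in pops:
        p0, a, b = mixture.get(pop, (0.2, 0.5, 0.8))
        for c in range(config.survey_n_per_pop):
            if rng.random() < p0:
                nec = 0.0
            else:
                nec = 5.0 * round(100.0 * rng.beta(a, b) / 5.0)
            records.append((f"{pop}-S{c + 1:02d}", pop, float(nec)))
    table = pd.DataFrame(records,
                         columns=["colony_id", "population", "necrosis_pct"])
    truth = {"mixture": {p: list(mixture.get(p, (0.2, 0.5, 0.8))) for p in pops}}
    return SurveySim(table, truth)
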