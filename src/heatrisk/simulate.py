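"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators provide everything the pipeline consumes without external
downloads: a seasonal daily maximum WBGT series with an injectable secular
warming trend, daily Poisson case counts drawn from a known dose-response
truth scaled by population, and smooth yearly population trajectories per
age group.  Every generator is a pure function of its spec and seed; a
single global seed fans out to independent per-stream seeds so climate,
cases and population can be regenerated separately.

The daily WBGT model is a cosine annual cycle plus linear trend plus i.i.d.
Gaussian noise:

    wbgt(d) = level + amplitude*cos(2*pi*(doy - peak)/365)
              + (trend/10)*(years since start) + eps,   eps ~ N(0, sd^2)

Tokyo-like defaults (annual mean 14 °C, amplitude 13 °C, peak around late
July, day-to-day sd 2 °C) give summer daily maxima in the upper 20s with
occasional days above 31 °C, matching the magnitudes of the observed Tokyo
series.  The generator makes no attempt to emulate heat-wave persistence
(autocorrelated noise) or humidity-temperature covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import ModelParams, predict_risk

__all__ = [
    "ClimateScenarioSpec",
    "TruthSpec",
    "simulate_climate",
    "simulate_cases",
    "simulate_population",
    "make_fixture_bundle",
    "tokyo_like_truth",
]

AGE_GROUPS = ("0-17", "18-64", "65+")


@dataclass(frozen=True)
class ClimateScenarioSpec:
    """Parameters of the synthetic daily WBGT generator."""

    start_year: int = 2015
    end_year: int = 2019
    mean_level: float = 14.0  # annual-mean daily max WBGT, °C
    amplitude: float = 13.0  # seasonal half-range, °C
    peak_doy: int = 205  # day of year of the seasonal peak (late July)
    trend_c_per_decade: float = 0.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")


@dataclass(frozen=True)
class TruthSpec:
    """True dose-response parameters and population trajectories per age group."""

    params: dict[str, ModelParams]
    base_population: dict[str, float]
    growth_rate: dict[str, float] = field(default_factory=dict)
    start_year: int = 2015

    def __post_init__(self):
        if not self.params:
            raise ValueError("at least one age group required")
        for g in self.params:
            if self.base_population.get(g, 0.0) <= 0:
                raise ValueError(f"base population for {g!r} must be > 0")

    def population(self, age_group: str, year) -> np.ndarray:
        """Geometric growth: base * (1 + rate)^(year - start_year)."""
        rate = self.growth_rate.get(age_group, 0.0)
        base = self.base_population[age_group]
        year = np.asarray(year)
        return base * (1.0 + rate) ** (year - self.start_year)


def tokyo_like_truth(start_year: int = 2015) -> TruthSpec:
    """A truth spec at the magnitudes of the Tokyo 2015-2019 study system.

    Exponential dose-response for each group with thresholds lowest for the
    elderly, and populations of 1.86 / 8.25 / 3.08 million (0-17 / 18-64 /
    65+) with mild secular drift.
    """
    return TruthSpec(
        params={
            "0-17": ModelParams(kind="exponential", beta1=0.5, r=0.40, tw=25.7),
            "18-64": ModelParams(kind="exponential", beta1=0.1, r=0.46, tw=23.7),
            "65+": ModelParams(kind="exponential", beta1=0.4, r=0.43, tw=22.7),
        },
        base_population={"0-17": 1.86e6, "18-64": 8.25e6, "65+": 3.08e6},
        growth_rate={"0-17": -0.005, "18-64": 0.0, "65+": 0.01},
        start_year=start_year,
    )


def _spawn_seeds(seed: int, n: int = 3) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def simulate_climate(spec: ClimateScenarioSpec) -> pd.DataFrame:
    """Daily maximum WBGT series for the spec's year range.

    Returns a DataFrame with ``date`` and ``wbgt_c``, one row per calendar
    day (Feb 29 included; downstream band counting drops it).
    """
    dates = pd.date_range(
        f"{spec.start_year}-01-01", f"{spec.end_year}-12-31", freq="D"
    )
    doy = dates.day_of_year.to_numpy(dtype=float)
    # leap years shift the DOY of fixed dates by one after Feb; the cycle is
    # smooth enough that a 365-day phase is adequate for synthetic data
    years_since = (dates - pd.Timestamp(f"{spec.start_year}-01-01")).days / 365.25
    rng = np.random.default_rng(_spawn_seeds(spec.seed)[0])
    wbgt = (
        spec.mean_level
        + spec.amplitude * np.cos(2.0 * np.pi * (doy - spec.peak_doy) / 365.0)
        + (spec.trend_c_per_decade / 10.0) * years_since
        + rng.normal(0.0, spec.noise_sd, size=len(dates))
    )
    return pd.DataFrame({"date": dates, "wbgt_c": wbgt})


def simulate_cases(
    wbgt_series: pd.DataFrame, truth: TruthSpec, seed: int
) -> pd.DataFrame:
    """Daily Poisson case counts per age group given a WBGT series.

    For each day and group, count ~ Poisson(risk(wbgt) * population/1e6)
    with the group's true dose-response and that calendar year's population.
    Returns the case-table dialect consumed by the fitting reader:
    ``date``, ``age_group``, ``count``, ``wbgt_c``, ``population``.
    """
    rng = np.random.default_rng(_spawn_seeds(seed)[1])
    dates = pd.to_datetime(wbgt_series["date"])
    T = wbgt_series["wbgt_c"].to_numpy(dtype=float)
    years = dates.dt.year.to_numpy()
    frames = []
    for group in truth.params:  # dict order is deterministic
        pop = truth.population(group, years)
        lam = predict_risk(truth.params[group], T) * pop / 1e6
        counts = rng.poisson(lam)
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "age_group": group,
                    "count": counts,
                    "wbgt_c": T,
                    "population": np.round(pop).astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_population(truth: TruthSpec, years) -> pd.DataFrame:
    """Yearly population per age group by exact geometric growth."""
    years = list(years)
    if not years:
        raise ValueError("years must be nonempty")
    rows = []
    for group in truth.params:
        pops = truth.population(group, np.asarray(years))
        for y, p in zip(years, pops):
            rows.append({"year": int(y), "age_group": group, "population": float(p)})
    return pd.DataFrame(rows)


def make_fixture_bundle(
    out_dir, profile: str = "tokyo-like", seed: int = 0
) -> dict[str, Path]:
    """Write a coherent climate / cases / population CSV bundle.

    ``profile="tokyo-like"`` emulates the study system's magnitudes over
    five full years (seasonal 65+ counts totalling thousands per year);
    ``profile="minimal"`` is a 30-day single-group bundle for fast tests.
    Files are byte-identical across runs with the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if profile == "tokyo-like":
        spec = ClimateScenarioSpec(start_year=2015, end_year=2019, seed=seed)
        truth = tokyo_like_truth(start_year=2015)
        years = range(2015, 2020)
    elif profile == "minimal":
        spec = ClimateScenarioSpec(
            start_year=2019, end_year=2019, seed=seed, mean_level=24.0, amplitude=6.0
        )
        truth = TruthSpec(
            params={"65+": ModelParams(kind="exponential", beta1=0.4, r=0.43, tw=22.7)},
            base_population={"65+": 3.08e6},
            start_year=2019,
        )
        years = [2019]
    else:
        raise ValueError("profile must be 'tokyo-like' or 'minimal'")

    climate = simulate_climate(spec)
    if profile == "minimal":
        climate = climate[(climate["date"] >= "2019-07-01") & (climate["date"] <= "2019-07-30")]
        climate = climate.reset_index(drop=True)
    cases = simulate_cases(climate, truth, seed)
    population = simulate_population(truth, years)

    paths = {
        "climate": out_dir / "climate.csv",
        "cases": out_dir / "cases.csv",
        "population": out_dir / "population.csv",
    }
    climate.assign(date=climate["date"].dt.strftime("%Y-%m-%d")).to_csv(
        paths["climate"], index=False, float_format="%.6f"
    )
    cases.assign(date=pd.to_datetime(cases["date"]).dt.strftime("%Y-%m-%d")).to_csv(
        paths["cases"], index=False, float_format="%.6f"
    )
    population.to_csv(paths["population"], index=False, float_format="%.1f")
    return paths
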