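"""Synthetic survival trials and seasonal monitoring series.

The raw data behind the study conditions — per-tank mortality counts and the
2003-2010 monitoring records — were never published, only their summaries.
This module generates data with the statistical structure the downstream
analysis assumes, so every stage is testable end to end:

* **Toxicity trials.** Each fish carries a latent tolerance quantile
  u ~ Uniform(0, 1) and dies by time t iff u < P(death | dose, t), where
  P(death | dose c, time t) = Phi(slope * (log10 c - log10 LC50(t))) and
  LC50(t) decays exponentially, LC50(t) = LC50_ref * exp(-k (t - t_ref)).
  Because P is non-decreasing in t, cumulative counts are monotone per tank
  by construction (independent per-time binomials would not be). Control
  tanks die only through the optional background-mortality rate, which also
  mixes into dosed tanks as p_obs = b + (1 - b) * p — the regime Abbott's
  correction undoes.

* **Seasonal series.** Each variable/season is drawn i.i.d. lognormal with
  a given log-location and log-scale (marginals only; the source summaries
  report no cross-variable covariance). Dates are placed in the matching
  calendar months so the season classifier reproduces the labels.

Defaults reproduce the study conditions: the seven-dose Cu grid with 10
fish per tank observed at 24/48/72/96 h, a 96-h LC50 of 0.655 mg/L decaying
at 0.0061 per hour, and seasonal specs matched to the monitoring-table
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .dose_response import ToxicityTrial
from .seasonal import DRY_MONTHS

__all__ = [
    "TrialDesign", "ProbitTruth", "SeasonSpec",
    "simulate_trial", "simulate_seasonal_series",
    "default_design", "default_truth", "default_season_specs",
]

#: Probit slope (per log10 dose) used when the truth does not specify one:
#: a moderately steep acute-metal dose-response.
DEFAULT_SLOPE = 4.0


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a static acute bioassay: dose grid, tank size, schedule."""

    concentrations: tuple[float, ...]
    n_per_tank: int = 10
    observation_times: tuple[float, ...] = datasets.OBSERVATION_TIMES_H
    control_included: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        t = np.asarray(self.observation_times, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be positive and strictly increasing")
        if self.n_per_tank < 1:
            raise ValueError("n_per_tank must be >= 1")


@dataclass(frozen=True)
class ProbitTruth:
    """Generating dose-response: probit in log10 dose, LC50 decaying in time."""

    lc50_at_ref_time: float
    slope: float = DEFAULT_SLOPE
    decay_rate: float = 0.0
    ref_time: float = 96.0
    background_mortality: float = 0.0
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if self.lc50_at_ref_time <= 0:
            raise ValueError("lc50_at_ref_time must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be non-negative")
        if not 0.0 <= self.background_mortality < 1.0:
            raise ValueError("background mortality must lie in [0, 1)")

    def lc50_at(self, time_h: float) -> float:
        return self.lc50_at_ref_time * math.exp(
            -self.decay_rate * (time_h - self.ref_time))

    def death_probability(self, concentration, time_h) -> np.ndarray:
        """P(dead by ``time_h`` | dose), background mortality mixed in."""
        c = np.asarray(concentration, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentration must be positive")
        lt = math.log(self.lc50_at(float(time_h)))
        z = self.slope * (np.log(c) - lt) / math.log(self.log_base)
        if np.isinf(self.slope):
            p = np.where(z > 0, 1.0, np.where(z < 0, 0.0, 0.5))
        else:
            p = stats.norm.cdf(z)
        b = self.background_mortality
        return b + (1.0 - b) * p


@dataclass(frozen=True)
class SeasonSpec:
    """Lognormal sampling law for one variable in one season."""

    variable: str
    season: str
    location: float  # mean of ln(value)
    scale: float     # sd of ln(value)
    n: int

    def __post_init__(self) -> None:
        if self.season not in ("dry", "wet"):
            raise ValueError(f"unknown season label: {self.season!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_moments(cls, variable: str, season: str, mean: float, sd: float,
                     n: int) -> "SeasonSpec":
        """Match the lognormal's arithmetic mean and SD."""
        if mean <= 0 or sd <= 0:
            raise ValueError("mean and sd must be positive")
        sigma2 = math.log1p((sd / mean) ** 2)
        return cls(variable=variable, season=season,
                   location=math.log(mean) - sigma2 / 2.0,
                   scale=math.sqrt(sigma2), n=n)

    @property
    def mean(self) -> float:
        return math.exp(self.location + self.scale**2 / 2.0)

    @property
    def sd(self) -> float:
        return self.mean * math.sqrt(math.expm1(self.scale**2))


def simulate_trial(design: TrialDesign, truth: ProbitTruth,
                   seed: int) -> ToxicityTrial:
    """Draw one bioassay: latent per-fish tolerances, cumulative counts.

    Each fish in tank i gets u ~ U(0,1); its cumulative death indicator at
    time t is u < P(death | c_i, t). With LC50 non-increasing in time the
    per-tank counts are non-decreasing pathwise. Identical seeds give
    identical trials.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(design.observation_times, dtype=float)
    deaths = np.empty((len(design.concentrations), times.size))
    for i, c in enumerate(design.concentrations):
        u = rng.uniform(size=design.n_per_tank)
        p_t = np.array([truth.death_probability(c, t) for t in times])
        deaths[i] = (u[None, :] < p_t[:, None]).sum(axis=1)
    kwargs: dict = {}
    if design.control_included:
        u = rng.uniform(size=design.n_per_tank)
        b = truth.background_mortality
        kwargs["control_n"] = design.n_per_tank
        kwargs["control_deaths"] = tuple(
            float((u < b).sum()) for _ in times)
    return ToxicityTrial(
        concentrations=tuple(float(c) for c in design.concentrations),
        n_exposed=tuple(float(design.n_per_tank) for _ in design.concentrations),
        times_h=tuple(float(t) for t in times),
        deaths=deaths,
        **kwargs,
    )


_WET_MONTHS = (11, 12, 1, 2, 3, 4)
_DRY_MONTHS_ORDERED = tuple(sorted(DRY_MONTHS))


def _season_dates(season: str, n: int, start_year: int) -> list[pd.Timestamp]:
    months = _DRY_MONTHS_ORDERED if season == "dry" else _WET_MONTHS
    out = []
    for i in range(n):
        month = months[i % len(months)]
        out.append(pd.Timestamp(year=start_year + i // len(months),
                                month=month, day=15))
    return out


def simulate_seasonal_series(specs: Sequence[SeasonSpec], seed: int,
                             start_year: int = 2003) -> pd.DataFrame:
    """Draw a monitoring table from per-variable per-season lognormal specs.

    One row per (season, sample index); a variable with fewer samples than
    the widest spec of its season is padded with NaN, mirroring the ragged
    counts of real monitoring tables. Dates fall in the season's calendar
    months so :func:`cutox.seasonal.classify_season` round-trips the label.
    """
    if not specs:
        raise ValueError("at least one SeasonSpec is required")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    frames: dict[str, pd.DataFrame] = {}
    for season in ("dry", "wet"):
        season_specs = [(s, c) for s, c in zip(specs, children)
                        if s.season == season]
        if not season_specs:
            continue
        n_rows = max(s.n for s, _ in season_specs)
        data: dict[str, np.ndarray] = {}
        for spec, child in season_specs:
            rng = np.random.default_rng(child)
            draws = rng.lognormal(mean=spec.location, sigma=spec.scale,
                                  size=spec.n)
            col = np.full(n_rows, np.nan)
            col[: spec.n] = draws
            data[spec.variable] = col
        frames[season] = pd.DataFrame(
            {"date": _season_dates(season, n_rows, start_year), **data})
    table = pd.concat(frames.values(), ignore_index=True)
    return table


def default_design() -> TrialDesign:
    """The study's bioassay layout: seven Cu doses, 10 fish, 24-96 h."""
    return TrialDesign(concentrations=datasets.TEST_CONCENTRATIONS,
                       n_per_tank=datasets.N_PER_TANK,
                       observation_times=datasets.OBSERVATION_TIMES_H,
                       control_included=True)


def default_truth() -> ProbitTruth:
    """Generating truth anchored to the study's 96-h LC50 and decay rate."""
    return ProbitTruth(lc50_at_ref_time=0.655, slope=DEFAULT_SLOPE,
                       decay_rate=datasets.DECAY_RATE_PER_H, ref_time=96.0)


def default_season_specs() -> list[SeasonSpec]:
    """Lognormal specs matched to the monitoring table's seasonal moments."""
    specs = []
    for variable, seasons in datasets.SEASONAL_SUMMARY.items():
        for season, (n, mean, _med, _max, _min, sd) in seasons.items():
            specs.append(SeasonSpec.from_moments(variable, season, mean, sd,
                                                 int(n)))
    return specs
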