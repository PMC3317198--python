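"""Dry/wet-season comparison of monitoring series.

A dryland-river monitoring record is split by calendar month into a dry
season (May-October, the low-flow months) and a wet season (November-April).
For each water-quality variable the two seasonal means are compared with the
dm statistic,

    dm = (x_bar - y_bar) / sqrt(ES_x**2 + ES_y**2),

where the standard errors ES are bootstrap estimates (B resamples with
replacement, each of the observed size). |dm| > 2 is taken as evidence that
the seasonal means differ. A closed-form variant accepts published
(mean, SE) summaries directly. Monthly hydrograph aggregation (mean, 10th
and 90th percentile discharge per calendar month) is included for flow
context.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DRY_MONTHS", "SeasonalSummary", "DmResult", "classify_season",
    "bootstrap_se", "dm_statistic", "dm_from_summary", "seasonal_table",
    "hydrograph_summary",
]

#: Calendar months of the dry (low-flow) season.
DRY_MONTHS: frozenset[int] = frozenset({5, 6, 7, 8, 9, 10})

DEFAULT_B = 2000

DM_THRESHOLD = 2.0


@dataclass(frozen=True)
class SeasonalSummary:
    """Descriptive statistics of one variable in one season."""

    variable: str
    season: str
    n: int
    mean: float
    median: float
    max: float
    min: float
    std: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.min <= self.median <= self.max:
            raise ValueError("min <= median <= max violated")
        if self.std < 0:
            raise ValueError("std must be non-negative")


@dataclass(frozen=True)
class DmResult:
    """dm statistic for one variable: dry vs wet difference of means."""

    variable: str
    mean_dry: float
    mean_wet: float
    se_dry: float
    se_wet: float
    dm: float
    significant: bool
    n_bootstrap: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.se_dry < 0 or self.se_wet < 0:
            raise ValueError("bootstrap SEs must be non-negative")
        if math.isfinite(self.dm) and self.significant != (abs(self.dm) > DM_THRESHOLD):
            raise ValueError("significance flag inconsistent with |dm| > 2")


def classify_season(date, dry_months: frozenset[int] = DRY_MONTHS) -> str:
    """Classify a date as ``"dry"`` (May-October) or ``"wet"`` (November-April).

    The boundary is the calendar month; ``dry_months`` can redefine it for
    rivers with a different hydrological year.
    """
    try:
        ts = pd.Timestamp(date)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date: {date!r}") from exc
    if pd.isna(ts):
        raise ValueError(f"unparseable date: {date!r}")
    return "dry" if ts.month in dry_months else "wet"


def bootstrap_se(values: Sequence[float], B: int = DEFAULT_B,
                 seed: int = 0) -> float:
    """Bootstrap standard error of the mean of ``values``.

    Draws ``B`` resamples with replacement, each of the observed size, and
    returns the standard deviation of the resampled means. Requires n >= 2.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("bootstrap SE needs at least 2 observations")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(B, v.size))
    means = v[idx].mean(axis=1)
    return float(means.std(ddof=1)) if B > 1 else 0.0


def dm_from_summary(mean_x: float, se_x: float, mean_y: float,
                    se_y: float) -> float:
    """Closed-form dm from published means and standard errors.

    With both SEs zero the statistic is 0 for equal means and signed
    infinity otherwise (flagging a degenerate comparison).
    """
    if se_x < 0 or se_y < 0:
        raise ValueError("standard errors must be non-negative")
    denom = math.hypot(se_x, se_y)
    diff = mean_x - mean_y
    if denom == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / denom


def dm_statistic(x: Sequence[float], y: Sequence[float], B: int = DEFAULT_B,
                 seed: int = 0, variable: str = "", standardize: bool = False,
                 ) -> DmResult:
    """dm statistic between two seasonal series with bootstrap SEs.

    Both series need n >= 2. The same resampling seed is applied to each
    series so that dm(x, y) == -dm(y, x) exactly. ``standardize`` divides
    both series by the pooled standard deviation first; the ratio is
    invariant to common rescaling, so this only matters for the reported
    means and SEs.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    xv, yv = xv[~np.isnan(xv)], yv[~np.isnan(yv)]
    if xv.size < 2 or yv.size < 2:
        raise ValueError("both series need at least 2 observations")
    if standardize:
        pooled_sd = np.concatenate([xv, yv]).std(ddof=1)
        if pooled_sd > 0:
            xv, yv = xv / pooled_sd, yv / pooled_sd
    se_x = bootstrap_se(xv, B=B, seed=seed)
    se_y = bootstrap_se(yv, B=B, seed=seed)
    dm = dm_from_summary(float(xv.mean()), se_x, float(yv.mean()), se_y)
    return DmResult(
        variable=variable, mean_dry=float(xv.mean()), mean_wet=float(yv.mean()),
        se_dry=se_x, se_wet=se_y, dm=dm,
        significant=bool(abs(dm) > DM_THRESHOLD) if math.isfinite(dm) else True,
        n_bootstrap=B, seed=seed,
    )


def seasonal_table(
    monitoring: pd.DataFrame,
    variables: Sequence[str] | None = None,
    B: int = DEFAULT_B,
    seed: int = 0,
    date_column: str = "date",
    dry_months: frozenset[int] = DRY_MONTHS,
) -> tuple[list[SeasonalSummary], list[DmResult]]:
    """Seasonal descriptive statistics plus a dm row per variable.

    Missing values are dropped per variable. A variable present in only one
    season gets its summaries but no dm entry; dm also needs >= 2 records
    in each season.
    """
    if date_column not in monitoring.columns:
        raise ValueError(f"monitoring table lacks a {date_column!r} column")
    df = monitoring.copy()
    df["_season"] = [classify_season(d, dry_months) for d in df[date_column]]
    if variables is None:
        variables = [c for c in df.columns
                     if c not in (date_column, "_season")
                     and pd.api.types.is_numeric_dtype(df[c])]
    summaries: list[SeasonalSummary] = []
    dms: list[DmResult] = []
    for var in variables:
        per_season: dict[str, np.ndarray] = {}
        for season in ("dry", "wet"):
            vals = df.loc[df["_season"] == season, var].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            per_season[season] = vals
            summaries.append(SeasonalSummary(
                variable=var, season=season, n=int(vals.size),
                mean=float(vals.mean()), median=float(np.median(vals)),
                max=float(vals.max()), min=float(vals.min()),
                std=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            ))
        if ("dry" in per_season and "wet" in per_season
                and per_season["dry"].size >= 2 and per_season["wet"].size >= 2):
            dms.append(dm_statistic(per_season["dry"], per_season["wet"],
                                    B=B, seed=seed, variable=var))
    return summaries, dms


def summaries_frame(summaries: Sequence[SeasonalSummary],
                    dms: Sequence[DmResult]) -> pd.DataFrame:
    """Flatten summaries + dm results into one tidy table (CSV-ready)."""
    rows = [vars(s) | {"statistic": "summary"} for s in summaries]
    for d in dms:
        rows.append({"variable": d.variable, "season": "dry-vs-wet",
                     "statistic": "dm", "mean": d.mean_dry - d.mean_wet,
                     "std": math.hypot(d.se_dry, d.se_wet),
                     "dm": d.dm, "significant": d.significant})
    return pd.DataFrame(rows)


def hydrograph_summary(discharge: pd.DataFrame, date_column: str = "date",
                       q_column: str = "Q_m3_s") -> pd.DataFrame:
    """Per-calendar-month discharge climatology: mean, 10th and 90th percentile.

    Aggregates across years; months with no observations are omitted with a
    warning. Percentiles use linear interpolation between order statistics.
    """
    df = discharge[[date_column, q_column]].dropna()
    if df.empty:
        raise ValueError("no discharge observations")
    months = pd.DatetimeIndex(pd.to_datetime(df[date_column])).month
    rows = []
    for m in range(1, 13):
        q = df.loc[months == m, q_column].to_numpy(dtype=float)
        if q.size == 0:
            warnings.warn(f"no discharge observations for month {m}; omitted")
            continue
        rows.append({"month": m, "n": int(q.size), "mean": float(q.mean()),
                     "p10": float(np.percentile(q, 10)),
                     "p90": float(np.percentile(q, 90))})
    return pd.DataFrame(rows)
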