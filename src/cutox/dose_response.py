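"""Probit dose-response analysis for acute toxicity bioassays.

The classical bioassay model: the probability that a fish dies by a fixed
observation time is P(death | dose c) = Phi(alpha + beta * log10 c), fitted
to dose-grouped cumulative mortality counts by binomial maximum likelihood
(Fisher scoring). Median lethal concentration LC50 — and the general LCp —
is read off the fitted line as 10**((Phi^-1(p) - alpha)/beta), with a 95%
confidence interval by the delta method on the log-dose scale (default) or
by Fieller's theorem. A separate helper fits the empirical exponential
decay of LC50 with exposure time, LC50(t) = a * exp(-k t), as ordinary
least squares of ln LC50 on t.

The dose metameter is log10 by convention; natural log is available through
``log_base``. A zero-dose control group never enters the probit likelihood;
it is used for Abbott's correction of treatment mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ToxicityTrial", "ProbitFit", "Lc50Estimate", "TimeDecayFit",
    "fit_probit", "lc_p", "abbott_correct", "fit_time_decay",
    "read_trial_csv", "write_trial_csv",
]

_MAX_ITER = 100
_LOGLIK_TOL = 1e-8
#: |beta| (per log10-dose) beyond which the response is treated as separated.
_SEPARATION_SLOPE = 75.0


@dataclass(frozen=True)
class ToxicityTrial:
    """Dose-grouped cumulative mortality counts at each observation time.

    ``deaths[i, j]`` is the cumulative number of deaths at dose
    ``concentrations[i]`` by time ``times_h[j]``; counts may be fractional
    after Abbott's correction. A control (zero-dose) group is held apart
    from the dosed groups.
    """

    concentrations: tuple[float, ...]
    n_exposed: tuple[float, ...]
    times_h: tuple[float, ...]
    deaths: np.ndarray  # shape (n_doses, n_times)
    control_n: float | None = None
    control_deaths: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "deaths", np.asarray(self.deaths, dtype=float))
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c <= 0):
            raise ValueError("dosed concentrations must be strictly positive")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be unique")
        if self.deaths.shape != (len(self.concentrations), len(self.times_h)):
            raise ValueError("deaths must have shape (n_doses, n_times)")
        n = np.asarray(self.n_exposed, dtype=float)[:, None]
        if np.any(self.deaths < 0) or np.any(self.deaths > n):
            raise ValueError("deaths must lie in [0, n_exposed]")
        if np.any(np.diff(self.deaths, axis=1) < -1e-12):
            raise ValueError("cumulative deaths must be non-decreasing in time")
        if (self.control_deaths is None) != (self.control_n is None):
            raise ValueError("control_n and control_deaths go together")
        if self.control_deaths is not None:
            cd = np.asarray(self.control_deaths, dtype=float)
            if len(cd) != len(self.times_h):
                raise ValueError("control_deaths must cover every time")
            if np.any(cd < 0) or np.any(cd > self.control_n):
                raise ValueError("control deaths must lie in [0, control_n]")

    @property
    def has_control(self) -> bool:
        return self.control_deaths is not None

    def deaths_at(self, time_h: float) -> np.ndarray:
        try:
            j = self.times_h.index(time_h)
        except ValueError:
            raise KeyError(f"time {time_h} h not observed; have {self.times_h}")
        return self.deaths[:, j]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"deaths_{_fmt_time(t)}h": self.deaths[:, j]
                for j, t in enumerate(self.times_h)}
        df = pd.DataFrame({"concentration_mg_L": self.concentrations,
                           "n": self.n_exposed, **cols})
        if self.has_control:
            ctl = {"concentration_mg_L": 0.0, "n": self.control_n,
                   **{f"deaths_{_fmt_time(t)}h": d
                      for t, d in zip(self.times_h, self.control_deaths)}}
            df = pd.concat([pd.DataFrame([ctl]), df], ignore_index=True)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ToxicityTrial":
        death_cols = [c for c in df.columns if c.startswith("deaths_")]
        if not death_cols or "concentration_mg_L" not in df or "n" not in df:
            raise ValueError(
                "trial table needs concentration_mg_L, n and deaths_<t>h columns")
        times = sorted(float(c[len("deaths_"):-1]) for c in death_cols)
        ordered = [f"deaths_{_fmt_time(t)}h" for t in times]
        conc = df["concentration_mg_L"].astype(float)
        dosed = df[conc > 0].sort_values("concentration_mg_L")
        ctl = df[conc == 0]
        kwargs: dict = {}
        if len(ctl) == 1:
            kwargs["control_n"] = float(ctl["n"].iloc[0])
            kwargs["control_deaths"] = tuple(ctl[ordered].iloc[0].astype(float))
        elif len(ctl) > 1:
            raise ValueError("at most one control (zero-dose) row allowed")
        return cls(
            concentrations=tuple(dosed["concentration_mg_L"].astype(float)),
            n_exposed=tuple(dosed["n"].astype(float)),
            times_h=tuple(times),
            deaths=dosed[ordered].to_numpy(dtype=float),
            **kwargs,
        )


def _fmt_time(t: float) -> str:
    return f"{t:g}"


@dataclass(frozen=True)
class ProbitFit:
    """Maximum-likelihood probit fit at one observation time."""

    alpha: float
    beta: float
    cov: np.ndarray  # 2x2 covariance of (alpha, beta)
    loglik: float
    converged: bool
    n_doses: int
    time_h: float
    log_base: float = 10.0
    separation: bool = False

    def predict(self, dose: np.ndarray) -> np.ndarray:
        """Fitted mortality probability at the given dose(s)."""
        x = np.log(np.asarray(dose, dtype=float)) / np.log(self.log_base)
        return stats.norm.cdf(self.alpha + self.beta * x)


@dataclass(frozen=True)
class Lc50Estimate:
    """LCp point estimate with confidence interval, on the dose scale."""

    time_h: float
    p: float
    point: float
    ci_low: float
    ci_high: float
    ci_method: str = "delta"
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class TimeDecayFit:
    """Exponential decay of LC50 with exposure time, LC50(t) = a exp(-k t)."""

    amplitude: float
    rate: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def lc50_at(self, time_h: float) -> float:
        return self.amplitude * math.exp(-self.rate * time_h)


def _binom_loglik(alpha, beta, x, y, n):
    eta = alpha + beta * x
    p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
    return np.sum(y * np.log(p) + (n - y) * np.log1p(-p))


def _start_values(x: np.ndarray, y: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    # Empirical-probit least squares on shrunk mortality fractions.
    q = (y + 0.5) / (n + 1.0)
    z = stats.norm.ppf(q)
    if np.ptp(x) == 0:
        return float(z.mean()), 1.0
    beta, alpha = np.polyfit(x, z, 1)
    if beta <= 0:
        beta = 1.0
    return float(alpha), float(beta)


def _grid_refine(x, y, n, alpha0, beta0, half_a=10.0, lo_b=1e-3, hi_b=None,
                 size=101, stages=6):
    """Bounded grid search for the likelihood maximum (fallback and oracle)."""
    hi_b = hi_b if hi_b is not None else _SEPARATION_SLOPE
    a_lo, a_hi = alpha0 - half_a, alpha0 + half_a
    b_lo, b_hi = lo_b, hi_b
    best = (alpha0, max(beta0, lo_b))
    for _ in range(stages):
        al = np.linspace(a_lo, a_hi, size)
        be = np.linspace(b_lo, b_hi, size)
        A, B = np.meshgrid(al, be, indexing="ij")
        eta = A[..., None] + B[..., None] * x
        p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
        ll = (y * np.log(p) + (n - y) * np.log1p(-p)).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(al[i]), float(be[j]))
        da, db = (a_hi - a_lo) / (size - 1), (b_hi - b_lo) / (size - 1)
        a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
        b_lo, b_hi = max(lo_b, best[1] - 2 * db), best[1] + 2 * db
    return best


def fit_probit(trial: ToxicityTrial, time_h: float, log_base: float = 10.0) -> ProbitFit:
    """Fit the probit dose-response at one observation time.

    Fisher scoring (iteratively reweighted least squares) on the binomial
    likelihood of P(death) = Phi(alpha + beta * log(dose)/log(log_base)).
    Doses with 0% or 100% mortality stay in the likelihood. On a separated
    dose grid (the MLE slope diverges) the fit is returned from a bounded
    grid search with ``separation=True`` and ``converged=False`` rather
    than raising.

    Raises
    ------
    ValueError
        If fewer than 2 dosed groups, or the response carries no
        information (every fish dead, or none).
    """
    if trial.has_control:
        cd = np.asarray(trial.control_deaths, dtype=float)
        if np.any(cd > 0):
            raise ValueError(
                "control mortality present: apply abbott_correct() first")
    y = np.asarray(trial.deaths_at(time_h), dtype=float)
    n = np.asarray(trial.n_exposed, dtype=float)
    x = np.log(np.asarray(trial.concentrations, dtype=float)) / np.log(log_base)
    if len(x) < 2:
        raise ValueError("at least 2 dosed groups are required")
    if y.sum() <= 0 or y.sum() >= n.sum():
        raise ValueError(
            "no partial mortality information: all-dead or all-alive trial")

    # Complete separation: every group is all-dead or all-alive and the
    # split is monotone in dose, so the MLE slope diverges.
    frac = y / n
    if np.all((y == 0) | (y == n)) and np.all(np.diff(frac) >= 0):
        a0, b0 = _start_values(x, y, n)
        alpha, beta = _grid_refine(x, y, n, a0, b0)
        ll = _binom_loglik(alpha, beta, x, y, n)
        eta = alpha + beta * x
        p = np.clip(stats.norm.cdf(eta), 1e-10, 1 - 1e-10)
        phi = stats.norm.pdf(eta)
        w = n * phi**2 / (p * (1 - p))
        X = np.column_stack([np.ones_like(x), x])
        try:
            cov = np.linalg.inv((X.T * w) @ X)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        return ProbitFit(alpha=alpha, beta=beta, cov=cov, loglik=float(ll),
                         converged=False, n_doses=len(x), time_h=float(time_h),
                         log_base=log_base, separation=True)

    alpha, beta = _start_values(x, y, n)
    ll = _binom_loglik(alpha, beta, x, y, n)
    converged = False
    X = np.column_stack([np.ones_like(x), x])
    for _ in range(_MAX_ITER):
        eta = alpha + beta * x
        p = np.clip(stats.norm.cdf(eta), 1e-10, 1 - 1e-10)
        phi = stats.norm.pdf(eta)
        w = n * phi**2 / (p * (1 - p))
        z = eta + (y / n - p) / np.maximum(phi, 1e-300)
        XtW = X.T * w
        try:
            coef = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        # Step-halve if the full scoring step degrades the likelihood.
        step = coef - np.array([alpha, beta])
        for damp in (1.0, 0.5, 0.25, 0.125, 0.0625):
            cand = np.array([alpha, beta]) + damp * step
            ll_new = _binom_loglik(cand[0], cand[1], x, y, n)
            if ll_new >= ll - 1e-12:
                break
        alpha, beta = float(cand[0]), float(cand[1])
        if abs(ll_new - ll) < _LOGLIK_TOL:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    separation = abs(beta) > _SEPARATION_SLOPE or not np.isfinite(ll)
    if not converged or separation:
        a0, b0 = _start_values(x, y, n)
        alpha, beta = _grid_refine(x, y, n, a0, b0)
        ll = _binom_loglik(alpha, beta, x, y, n)
        separation = beta >= _SEPARATION_SLOPE * 0.99
        converged = False if separation else converged

    eta = alpha + beta * x
    p = np.clip(stats.norm.cdf(eta), 1e-10, 1 - 1e-10)
    phi = stats.norm.pdf(eta)
    w = n * phi**2 / (p * (1 - p))
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return ProbitFit(alpha=alpha, beta=beta, cov=cov, loglik=float(ll),
                     converged=bool(converged), n_doses=len(x),
                     time_h=float(time_h), log_base=log_base,
                     separation=bool(separation))


def lc_p(fit: ProbitFit, p: float = 0.5, method: str = "delta",
         level: float = 0.95) -> Lc50Estimate:
    """Lethal concentration for mortality fraction ``p`` with its CI.

    The point estimate is base**((Phi^-1(p) - alpha)/beta). The default CI
    is the delta method on the log-dose scale; ``method="fieller"`` inverts
    the score-band quadratic instead (unbounded Fieller sets fall back to
    wide finite bounds spanning the delta interval).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if fit.beta <= 0:
        raise ValueError("non-positive slope: response is not monotone increasing")
    if fit.separation:
        raise ValueError("separated fit: LCp interval is undefined")
    zp = stats.norm.ppf(p)
    m = (zp - fit.alpha) / fit.beta  # log-dose at fraction p
    zc = stats.norm.ppf(0.5 + level / 2)
    v = fit.cov
    if method == "delta":
        grad = np.array([-1.0 / fit.beta, -m / fit.beta])
        var_m = float(grad @ v @ grad)
        half = zc * math.sqrt(max(var_m, 0.0))
        lo, hi = m - half, m + half
    elif method == "fieller":
        a_q = fit.beta**2 - zc**2 * v[1, 1]
        b_q = 2 * (fit.beta * (fit.alpha - zp) - zc**2 * v[0, 1])
        c_q = (fit.alpha - zp) ** 2 - zc**2 * v[0, 0]
        disc = b_q**2 - 4 * a_q * c_q
        if a_q > 0 and disc >= 0:
            r = math.sqrt(disc)
            lo, hi = (-b_q - r) / (2 * a_q), (-b_q + r) / (2 * a_q)
        else:  # unbounded confidence set
            grad = np.array([-1.0 / fit.beta, -m / fit.beta])
            half = zc * math.sqrt(max(float(grad @ v @ grad), 0.0))
            lo, hi = m - 10 * half, m + 10 * half
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    base = fit.log_base
    lo, hi = max(lo, -300.0), min(hi, 300.0)
    return Lc50Estimate(time_h=fit.time_h, p=p, point=base**m,
                        ci_low=base**lo, ci_high=base**hi,
                        ci_method=method, level=level)


def abbott_correct(trial: ToxicityTrial) -> ToxicityTrial:
    """Rescale treatment mortality for natural (control) mortality.

    Abbott's formula p' = (p - c)/(1 - c) per observation time, with c the
    control mortality fraction at that time. Zero control mortality returns
    the input unchanged. Corrected counts are clipped to [0, n] and kept
    cumulative in time.
    """
    if not trial.has_control:
        raise ValueError("Abbott's correction requires a control group")
    c = np.asarray(trial.control_deaths, dtype=float) / trial.control_n
    if np.any(c >= 1.0):
        raise ValueError("complete control mortality: trial is invalid")
    if np.all(c == 0):
        return trial
    n = np.asarray(trial.n_exposed, dtype=float)[:, None]
    p = trial.deaths / n
    p_corr = np.clip((p - c[None, :]) / (1.0 - c[None, :]), 0.0, 1.0)
    deaths = np.maximum.accumulate(p_corr * n, axis=1)
    return replace(trial, deaths=deaths,
                   control_deaths=tuple(0.0 for _ in trial.times_h))


def fit_time_decay(
    estimates: Sequence[Lc50Estimate] | Iterable[tuple[float, float]],
) -> TimeDecayFit:
    """Fit LC50(t) = a * exp(-k t) by OLS of ln LC50 on exposure time.

    Accepts Lc50Estimate objects or raw (time_h, lc50) pairs; needs at
    least 3 points, all LC50s positive. ``r_squared`` is reported on the
    fitting (ln) scale.
    """
    pairs = [(e.time_h, e.point) if isinstance(e, Lc50Estimate) else (e[0], e[1])
             for e in estimates]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (time, LC50) points")
    t = np.array([q[0] for q in pairs], dtype=float)
    lc = np.array([q[1] for q in pairs], dtype=float)
    if np.any(lc <= 0):
        raise ValueError("LC50 values must be positive for the log-linear fit")
    ly = np.log(lc)
    slope, intercept = np.polyfit(t, ly, 1)
    resid = ly - (intercept + slope * t)
    sst = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return TimeDecayFit(amplitude=float(np.exp(intercept)), rate=float(-slope),
                        r_squared=min(max(r2, 0.0), 1.0), n_points=len(pairs))


def read_trial_csv(path) -> ToxicityTrial:
    return ToxicityTrial.from_frame(pd.read_csv(path))


def write_trial_csv(trial: ToxicityTrial, path) -> None:
    trial.to_frame().to_csv(path, index=False)
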