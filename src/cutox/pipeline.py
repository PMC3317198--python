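"""End-to-end analysis pipeline and report assembly.

Chains the full computational sequence of an acute copper-toxicity study:
survival trial (simulated or read from CSV) -> probit LC50 per observation
time -> exponential LC50-time decay fit -> hardness normalization against
the test-water chemistry -> copper partitioning -> seasonal dry/wet
comparison with dm flags. Everything is seeded and the report is a plain
dict serializable to JSON; re-running with the same configuration yields
byte-identical output.

``reference_report`` runs the deterministic desk portion on the published
inputs alone (printed LC50 series and sampling-date chemistry) with no
simulation, for cross-study comparison of the headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import datasets, synthetic, water_chemistry
from .dose_response import (ToxicityTrial, abbott_correct, fit_probit,
                            fit_time_decay, lc_p, read_trial_csv)
from .seasonal import DRY_MONTHS, hydrograph_summary, seasonal_table

__all__ = ["RunConfig", "run_pipeline", "reference_report", "validate_monitoring"]

REQUIRED_MONITORING = ["date", "Ca_mg_L", "Mg_mg_L", "TSS_mg_L",
                       "TCu_mg_L", "DCu_mg_L"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every field lands in the report."""

    seed: int = 0
    trial_csv: Optional[str] = None
    monitoring_csv: Optional[str] = None
    B: int = 2000
    ci_method: str = "delta"
    hardness_exponent: float = water_chemistry.EPA_HARDNESS_EXPONENT
    ref_hardness: float = water_chemistry.REFERENCE_HARDNESS
    dry_months: tuple[int, ...] = tuple(sorted(DRY_MONTHS))
    lc50_times_h: tuple[float, ...] = datasets.OBSERVATION_TIMES_H

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dry_months", "lc50_times_h"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_monitoring(df: pd.DataFrame) -> None:
    """Raise with an itemized message if the monitoring schema is violated."""
    missing = [c for c in REQUIRED_MONITORING if c not in df.columns]
    if missing:
        raise ValueError(
            "monitoring table is missing required columns: " + ", ".join(missing))


def _lc50_table(trial: ToxicityTrial, times, ci_method: str) -> list[dict]:
    rows = []
    for t in times:
        fit = fit_probit(trial, t)
        est = lc_p(fit, 0.5, method=ci_method)
        rows.append({
            "time_h": t, "lc50": est.point, "ci_low": est.ci_low,
            "ci_high": est.ci_high, "alpha": fit.alpha, "beta": fit.beta,
            "converged": fit.converged, "method": ci_method,
        })
    return rows


def _chemistry_block(chem: dict, config: RunConfig, lc50_96h: float) -> dict:
    sample = water_chemistry.WaterSample(
        tss=chem["TSS_mg_L"], ca=chem["Ca_mg_L"], mg=chem["Mg_mg_L"],
        tcu=chem["TCu_mg_L"], dcu=chem["DCu_mg_L"])
    hard = sample.hardness
    part = water_chemistry.partition(sample)
    return {
        "hardness_mgCaCO3_L": hard,
        "ca_mg_molar_ratio": water_chemistry.ca_mg_molar_ratio(
            chem["Ca_mg_L"], chem["Mg_mg_L"]),
        "lc50_96h_mg_L": lc50_96h,
        "lc50_normalized_mg_L": water_chemistry.normalize_lc50_hardness(
            lc50_96h, hard, config.ref_hardness, config.hardness_exponent),
        "soft_water_lc50_mg_L": datasets.SOFT_WATER_LC50,
        "soft_water_lc50_normalized_mg_L": water_chemistry.normalize_lc50_hardness(
            datasets.SOFT_WATER_LC50, datasets.SOFT_WATER_HARDNESS,
            config.ref_hardness, config.hardness_exponent),
        "pcu_mg_mg": part.pcu,
        "kd": part.kd,
        "kd_blm_monte": part.kd_blm_monte,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and return the report as a plain dict.

    Without input CSVs the trial and monitoring table are simulated under
    the default study conditions using ``config.seed``; with CSVs the files
    are validated and used instead.
    """
    rng_seed = int(config.seed)
    dry = frozenset(config.dry_months)

    if config.trial_csv:
        trial = read_trial_csv(config.trial_csv)
    else:
        trial = synthetic.simulate_trial(
            synthetic.default_design(), synthetic.default_truth(), rng_seed)
    if trial.has_control and any(d > 0 for d in trial.control_deaths):
        trial = abbott_correct(trial)

    times = [t for t in config.lc50_times_h if t in trial.times_h]
    lc50_rows = _lc50_table(trial, times, config.ci_method)
    decay = fit_time_decay([(r["time_h"], r["lc50"]) for r in lc50_rows])

    lc50_96h = next((r["lc50"] for r in lc50_rows if r["time_h"] == 96.0),
                    lc50_rows[-1]["lc50"])
    chemistry = _chemistry_block(datasets.SAMPLING_DATE_CHEMISTRY, config,
                                 lc50_96h)

    if config.monitoring_csv:
        monitoring = pd.read_csv(config.monitoring_csv)
        validate_monitoring(monitoring)
    else:
        monitoring = synthetic.simulate_seasonal_series(
            synthetic.default_season_specs(), rng_seed)
    summaries, dms = seasonal_table(monitoring, B=config.B, seed=rng_seed,
                                    dry_months=dry)
    hydro = (hydrograph_summary(monitoring)
             if "Q_m3_s" in monitoring.columns else None)

    return {
        "config": dataclasses.asdict(config),
        "trial": trial.to_frame().to_dict(orient="list"),
        "lc50_by_time": lc50_rows,
        "time_decay": dataclasses.asdict(decay),
        "water_chemistry": chemistry,
        "seasonal_summaries": [dataclasses.asdict(s) for s in summaries],
        "dm": [dataclasses.asdict(d) for d in dms],
        "hydrograph": None if hydro is None else hydro.to_dict(orient="list"),
    }


def reference_report(config: RunConfig | None = None) -> dict:
    """Desk recomputation on the published inputs only (no simulation).

    Uses the printed LC50 series for the decay fit and the sampling-date
    chemistry for normalization, molar ratio and partitioning — the
    deterministic headline numbers of the analysis.
    """
    config = config or RunConfig()
    pairs = [(t, rec["lc50"]) for t, rec in sorted(datasets.LC50_SERIES.items())]
    decay = fit_time_decay(pairs)
    chemistry = _chemistry_block(datasets.SAMPLING_DATE_CHEMISTRY, config,
                                 datasets.LC50_SERIES[96.0]["lc50"])
    return {
        "config": dataclasses.asdict(config),
        "lc50_by_time": [{"time_h": t, "lc50": lc} for t, lc in pairs],
        "time_decay": dataclasses.asdict(decay),
        "water_chemistry": chemistry,
    }


def render_text(report: dict) -> str:
    """Human-readable summary of a pipeline or reference report."""
    lines = ["Acute Cu toxicity report", "=" * 24]
    if "lc50_by_time" in report:
        lines.append("LC50 by exposure time (mg/L):")
        for r in report["lc50_by_time"]:
            ci = (f"  [{r['ci_low']:.3f}, {r['ci_high']:.3f}]"
                  if "ci_low" in r else "")
            lines.append(f"  {r['time_h']:5.0f} h  {r['lc50']:.3f}{ci}")
    if "time_decay" in report:
        d = report["time_decay"]
        lines.append(
            f"Decay fit: LC50(t) = {d['amplitude']:.4f} * exp(-{d['rate']:.4f} t), "
            f"R^2 = {d['r_squared']:.4f} (log scale)")
    if "water_chemistry" in report:
        c = report["water_chemistry"]
        lines += [
            f"Test-water hardness: {c['hardness_mgCaCO3_L']:.1f} mg CaCO3/L "
            f"(Ca:Mg molar {c['ca_mg_molar_ratio']:.2f})",
            f"96-h LC50 {c['lc50_96h_mg_L']:.3f} mg/L -> "
            f"{c['lc50_normalized_mg_L']:.2f} mg/L at reference hardness",
            f"Soft-water LC50 {c['soft_water_lc50_mg_L']:.3f} mg/L -> "
            f"{c['soft_water_lc50_normalized_mg_L']:.2f} mg/L",
            f"P.Cu {c['pcu_mg_mg']:.3g} mg/mg, Kd {c['kd']:.3g}, "
            f"BLM-MONTE Kd {c['kd_blm_monte']:.3g}",
        ]
    if report.get("dm"):
        lines.append("Seasonal dm (dry vs wet, |dm| > 2 significant):")
        for d in report["dm"]:
            flag = "*" if d["significant"] else " "
            lines.append(f"  {d['variable']:16s} dm = {d['dm']:7.2f} {flag}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
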