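"""Hardness, ion-ratio, LC50 normalization and Cu partitioning calculations.

Hardness is expressed as CaCO3 equivalents of dissolved Ca and Mg
(Standard Methods coefficients 2.497 and 4.118). Acute LC50s measured at
different hardness are brought to a common reference with the US EPA
ambient-water-quality-criteria conversion for copper,

    LC50(H_ref) = LC50 * (H_ref / H) ** b,   b = 0.9422 by default,

which is the exp/ln form of the criteria document's slope correction.
Solid/solution partitioning of copper uses particulate Cu per unit
suspended solid, P.Cu = (T.Cu - D.Cu)/TSS (mg Cu per mg TSS), the partition
ratio Kd = P.Cu/D.Cu, and the empirical BLM-MONTE relation
Kd = 1.04e6 * TSS**-0.7436.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: CaCO3-equivalence factors, mg CaCO3 per mg ion (Standard Methods).
HARDNESS_CA_COEF = 2.497
HARDNESS_MG_COEF = 4.118

#: Atomic masses (g/mol).
CA_ATOMIC_MASS = 40.078
MG_ATOMIC_MASS = 24.305

#: US EPA hardness-slope exponent for copper.
EPA_HARDNESS_EXPONENT = 0.9422

#: Reference hardness (mg CaCO3/L) for cross-study comparison.
REFERENCE_HARDNESS = 50.0

#: BLM-MONTE empirical Kd-TSS relation coefficients.
BLM_MONTE_COEF = 1.04e6
BLM_MONTE_EXPONENT = -0.7436

MONITORING_COLUMNS = [
    "date", "Q_m3_s", "pH", "T_C", "TSS_mg_L", "TDS_mg_L", "Ca_mg_L",
    "Mg_mg_L", "Na_mg_L", "K_mg_L", "SO4_mg_L", "Cl_mg_L", "Alk_mgCaCO3_L",
    "DOC_mg_L", "TCu_mg_L", "DCu_mg_L",
]


@dataclass(frozen=True)
class WaterSample:
    """One monitoring record of the river water.

    Concentrations in mg/L, alkalinity as mg CaCO3/L, discharge in m3/s.
    ``tcu``/``dcu`` are total and dissolved copper.
    """

    date: Optional[str] = None
    q: Optional[float] = None
    ph: Optional[float] = None
    temperature: Optional[float] = None
    tss: Optional[float] = None
    tds: Optional[float] = None
    ca: Optional[float] = None
    mg: Optional[float] = None
    na: Optional[float] = None
    k: Optional[float] = None
    so4: Optional[float] = None
    cl: Optional[float] = None
    alkalinity: Optional[float] = None
    doc: Optional[float] = None
    tcu: Optional[float] = None
    dcu: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tss", "tds", "ca", "mg", "na", "k", "so4", "cl",
                     "alkalinity", "doc", "tcu", "dcu"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.ph is not None and not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH outside [0, 14]: {self.ph}")
        if (self.tcu is not None and self.dcu is not None
                and self.dcu > self.tcu):
            raise ValueError(
                f"dissolved Cu ({self.dcu}) exceeds total Cu ({self.tcu})")

    @property
    def hardness(self) -> float:
        if self.ca is None or self.mg is None:
            raise ValueError("Ca and Mg required to compute hardness")
        return hardness(self.ca, self.mg)


@dataclass(frozen=True)
class PartitionResult:
    """Copper solid/solution partitioning for one sample.

    ``pcu`` is particulate copper per unit solid in mg Cu per mg TSS
    (multiply by 1e6 for ug/g); ``kd`` is the measured partition ratio
    P.Cu/D.Cu; ``kd_blm_monte`` is the empirical TSS-only estimate.
    ``kd`` is None when dissolved copper is zero (ratio undefined).
    """

    pcu: float
    kd: Optional[float]
    kd_blm_monte: float

    @property
    def pcu_ug_per_g(self) -> float:
        return self.pcu * 1e6


def hardness(ca: float, mg: float) -> float:
    """Water hardness (mg CaCO3/L) from dissolved Ca and Mg (mg/L)."""
    ca = np.asarray(ca, dtype=float)
    mg = np.asarray(mg, dtype=float)
    if np.any(ca < 0) or np.any(mg < 0):
        raise ValueError("Ca and Mg concentrations must be non-negative")
    out = HARDNESS_CA_COEF * ca + HARDNESS_MG_COEF * mg
    return float(out) if out.ndim == 0 else out


def normalize_lc50_hardness(
    lc50: float,
    hardness_value: float,
    ref_hardness: float = REFERENCE_HARDNESS,
    exponent: float = EPA_HARDNESS_EXPONENT,
) -> float:
    """Convert an acute LC50 to a reference hardness via the EPA slope.

    Parameters
    ----------
    lc50 : measured LC50 (mg/L) at ``hardness_value``.
    hardness_value : test-water hardness (mg CaCO3/L), > 0.
    ref_hardness : target hardness, default 50 mg CaCO3/L.
    exponent : pooled hardness slope on the ln-ln scale (0.9422 for Cu).
    """
    lc50 = np.asarray(lc50, dtype=float)
    if np.any(lc50 <= 0):
        raise ValueError("LC50 must be positive")
    if np.any(np.asarray(hardness_value) <= 0) or ref_hardness <= 0:
        raise ValueError("hardness must be positive")
    out = lc50 * (ref_hardness / np.asarray(hardness_value)) ** exponent
    return float(out) if out.ndim == 0 else out


def ca_mg_molar_ratio(ca: float, mg: float) -> float:
    """Molar Ca:Mg ratio from mass concentrations (mg/L)."""
    mg_arr = np.asarray(mg, dtype=float)
    if np.any(mg_arr <= 0):
        raise ValueError("Mg must be positive to form the molar ratio")
    out = (np.asarray(ca, dtype=float) / CA_ATOMIC_MASS) / (mg_arr / MG_ATOMIC_MASS)
    return float(out) if out.ndim == 0 else out


def kd_blm_monte(tss: float) -> float:
    """Empirical BLM-MONTE partition coefficient from TSS (mg/L)."""
    tss = np.asarray(tss, dtype=float)
    if np.any(tss <= 0):
        raise ValueError("TSS must be positive")
    out = BLM_MONTE_COEF * tss ** BLM_MONTE_EXPONENT
    return float(out) if out.ndim == 0 else out


def partition(sample: WaterSample) -> PartitionResult:
    """Compute P.Cu, Kd and the BLM-MONTE Kd for one monitoring record.

    Requires TSS > 0 and T.Cu >= D.Cu. ``kd`` is returned as None (flagged
    missing) when dissolved copper is zero rather than silently set to 0.
    """
    if sample.tss is None or sample.tcu is None or sample.dcu is None:
        raise ValueError("TSS, total Cu and dissolved Cu are all required")
    if sample.tss <= 0:
        raise ValueError("TSS must be positive to compute P.Cu")
    pcu = (sample.tcu - sample.dcu) / sample.tss
    kd = pcu / sample.dcu if sample.dcu > 0 else None
    return PartitionResult(pcu=pcu, kd=kd, kd_blm_monte=kd_blm_monte(sample.tss))


def derive_columns(monitoring: pd.DataFrame) -> pd.DataFrame:
    """Append derived chemistry columns to a monitoring table.

    Adds ``hardness_mgCaCO3_L``, ``ca_mg_molar``, ``PCu_mg_mg``, ``Kd`` and
    ``Kd_blm_monte``; rows with missing or degenerate inputs get NaN in the
    affected derived column.
    """
    out = monitoring.copy()
    ca = out["Ca_mg_L"].astype(float)
    mg = out["Mg_mg_L"].astype(float)
    out["hardness_mgCaCO3_L"] = HARDNESS_CA_COEF * ca + HARDNESS_MG_COEF * mg
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ca_mg_molar"] = np.where(
            mg > 0, (ca / CA_ATOMIC_MASS) / (mg / MG_ATOMIC_MASS), np.nan)
        tss = out["TSS_mg_L"].astype(float)
        tcu = out["TCu_mg_L"].astype(float)
        dcu = out["DCu_mg_L"].astype(float)
        pcu = np.where(tss > 0, (tcu - dcu) / tss, np.nan)
        out["PCu_mg_mg"] = pcu
        out["Kd"] = np.where(dcu > 0, pcu / dcu, np.nan)
        out["Kd_blm_monte"] = np.where(
            tss > 0, BLM_MONTE_COEF * tss ** BLM_MONTE_EXPONENT, np.nan)
    return out


def sample_from_row(row: pd.Series) -> WaterSample:
    """Build a WaterSample from one monitoring-CSV row."""
    def get(col: str) -> Optional[float]:
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    return WaterSample(
        date=str(row.get("date")) if row.get("date") is not None else None,
        q=get("Q_m3_s"), ph=get("pH"), temperature=get("T_C"),
        tss=get("TSS_mg_L"), tds=get("TDS_mg_L"), ca=get("Ca_mg_L"),
        mg=get("Mg_mg_L"), na=get("Na_mg_L"), k=get("K_mg_L"),
        so4=get("SO4_mg_L"), cl=get("Cl_mg_L"), alkalinity=get("Alk_mgCaCO3_L"),
        doc=get("DOC_mg_L"), tcu=get("TCu_mg_L"), dcu=get("DCu_mg_L"),
    )
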