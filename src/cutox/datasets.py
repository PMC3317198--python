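"""Published reference inputs from the Pilcomayo River copper-toxicity study.

These are the printed inputs of the original 96-h acute Cu bioassay on
*Cnesterodon decemmaculatus* and the Misión La Paz monitoring record: the
tested dose grid, the PROBIT LC50 series over exposure time, the sampling-date
water chemistry, and the seasonal descriptive statistics (dry = May-October,
wet = November-April) of the 2003-2010 monitoring series. Raw per-tank
mortality counts and raw monitoring records were not published; the synthetic
generators in :mod:`cutox.synthetic` emulate them from these summaries.
"""

from __future__ import annotations

# Dissolved Cu doses tested (mg/L), seven concentrations plus an untreated control.
TEST_CONCENTRATIONS: tuple[float, ...] = (0.05, 0.19, 0.39, 0.61, 0.73, 1.01, 1.42)

N_PER_TANK: int = 10

OBSERVATION_TIMES_H: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0)

# PROBIT LC50 (mg/L) with 95% CI (low, high) at each observation time.
LC50_SERIES: dict[float, dict[str, float]] = {
    24.0: {"lc50": 1.039, "ci_low": 0.245, "ci_high": 1.288},
    48.0: {"lc50": 0.792, "ci_low": 0.622, "ci_high": 0.962},
    72.0: {"lc50": 0.734, "ci_low": 0.561, "ci_high": 0.908},
    96.0: {"lc50": 0.655, "ci_low": 0.488, "ci_high": 0.823},
}

# Exponential decay of LC50 with exposure time fitted in the original study:
# LC50(t) = 1.1428 * exp(-0.0061 t), R^2 = 0.9219 on the log scale.
DECAY_AMPLITUDE: float = 1.1428
DECAY_RATE_PER_H: float = 0.0061
DECAY_R_SQUARED: float = 0.9219

# 96-h LC50 reported for the same species in synthetic soft water
# (hardness 67.66 mg CaCO3/L) by an earlier study.
SOFT_WATER_LC50: float = 0.155
SOFT_WATER_HARDNESS: float = 67.66

# Water chemistry of the toxicity-test water (sampling date, May 2009).
SAMPLING_DATE_CHEMISTRY: dict[str, float] = {
    "Q_m3_s": 75.20,
    "pH": 7.67,
    "T_C": 21.43,
    "TSS_mg_L": 1637.0,
    "TDS_mg_L": 517.0,
    "Ca_mg_L": 73.33,
    "Mg_mg_L": 30.5,
    "SO4_mg_L": 207.3,
    "Alk_mgCaCO3_L": 110.0,
    "Cl_mg_L": 101.0,
    "Na_mg_L": 65.2,
    "K_mg_L": 5.1,
    "DOC_mg_L": 4.4,
    "TCu_mg_L": 0.07,
    "DCu_mg_L": 0.001,
}

# Seasonal descriptive statistics of the 2003-2010 monitoring series.
# Per variable: {season: (n, mean, median, max, min, std)}. DOC has no
# wet-season record. P.Cu is tabulated in ug/kg; all others in the units of
# the monitoring CSV schema.
SEASONAL_SUMMARY: dict[str, dict[str, tuple[float, ...]]] = {
    "Q_m3_s": {"dry": (14, 57.18, 53.22, 161.2, 6.45, 41.40),
               "wet": (13, 248.4, 219.07, 712.77, 6.65, 195.22)},
    "pH": {"dry": (14, 7.87, 7.91, 8.1, 7.31, 0.20),
           "wet": (13, 7.70, 7.65, 8.33, 7.27, 0.27)},
    "T_C": {"dry": (11, 17.54, 16.9, 25.8, 11.8, 4.36),
            "wet": (8, 25.35, 27.15, 28.2, 17.7, 3.68)},
    "TSS_mg_L": {"dry": (13, 1582.95, 1147.0, 8181.0, 92.0, 2178.71),
                 "wet": (10, 14760.2, 8990.5, 53960.0, 240.0, 17298.53)},
    "TDS_mg_L": {"dry": (11, 845.7, 847.0, 1114.0, 517.0, 211.85),
                 "wet": (13, 469.46, 436.0, 1168.0, 170.0, 255.60)},
    "Ca_mg_L": {"dry": (14, 80.6, 79.0, 150.2, 44.0, 28.64),
                "wet": (13, 51.67, 44.0, 91.0, 19.0, 23.0)},
    "Mg_mg_L": {"dry": (14, 35.22, 37.75, 52.0, 9.4, 11.05),
                "wet": (10, 17.35, 14.5, 36.0, 3.4, 10.01)},
    "SO4_mg_L": {"dry": (12, 292.09, 278.0, 399.7, 190.0, 71.02),
                 "wet": (11, 149.09, 135.0, 376.0, 59.0, 87.87)},
    "Alk_mgCaCO3_L": {"dry": (12, 126.43, 121.5, 210.0, 91.0, 30.39),
                      "wet": (11, 108.71, 100.0, 182.0, 57.6, 33.07)},
    "Cl_mg_L": {"dry": (12, 164.91, 187.5, 243.0, 45.0, 61.53),
                "wet": (11, 56.85, 32.0, 268.0, 20.0, 71.45)},
    "Na_mg_L": {"dry": (14, 125.97, 120.5, 207.0, 70.0, 43.06),
                "wet": (13, 48.88, 36.0, 131.0, 18.0, 31.33)},
    "K_mg_L": {"dry": (14, 6.6, 6.55, 12.0, 3.2, 2.29),
               "wet": (13, 5.69, 5.0, 9.9, 3.2, 2.38)},
    "DOC_mg_L": {"dry": (6, 5.27, 5.06, 10.8, 2.2, 3.09)},
    "TCu_mg_L": {"dry": (13, 0.05, 0.03, 0.18, 0.01, 0.04),
                 "wet": (12, 0.16, 0.11, 0.458, 0.026, 0.15)},
    "PCu_ug_kg": {"dry": (12, 61.30, 34.37, 232.75, 11.43, 72.5),
                  "wet": (9, 26.58, 24.93, 53.78, 2.724, 18.75)},
    "DCu_mg_L": {"dry": (14, 0.0027, 0.002, 0.0067, 0.001, 0.001),
                 "wet": (13, 0.0025, 0.0012, 0.01, 0.0009, 0.002)},
}

# dm statistic (dry vs wet standardized difference of means, |dm|>2
# significant) as reported for the same table, in the same variable order.
REPORTED_DM: dict[str, float] = {
    "Q_m3_s": -3.8,
    "pH": 1.88,
    "T_C": -4.36,
    "TSS_mg_L": -2.49,
    "TDS_mg_L": 4.07,
    "Ca_mg_L": 3.09,
    "Mg_mg_L": 4.38,
    "SO4_mg_L": 4.53,
    "Alk_mgCaCO3_L": 1.41,
    "Cl_mg_L": 4.04,
    "Na_mg_L": 5.79,
    "K_mg_L": 1.07,
    "TCu_mg_L": -2.70,
    "PCu_ug_kg": 1.73,
    "DCu_mg_L": 0.14,
}


def summary_moments(variable: str, season: str) -> tuple[int, float, float]:
    """Return (n, mean, std) for one variable/season of the monitoring summary."""
    n, mean, _median, _max, _min, std = SEASONAL_SUMMARY[variable][season]
    return int(n), mean, std
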