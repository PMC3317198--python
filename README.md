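# cutox

Acute copper-toxicity analysis for seasonal rivers: probit LC50
estimation, LC50–time decay, hardness normalization, copper
solid/solution partitioning, and bootstrap-based dry/wet-season
comparison of water chemistry.

The package targets ecotoxicologists and water-quality analysts working
with acute bioassays in waters whose chemistry swings with the
hydrological cycle — the motivating case is a 96-h copper bioassay on the
small neotropical fish *Cnesterodon decemmaculatus* in hard, sediment-laden
Pilcomayo River water, compared across studies and seasons. Because the
raw survival counts and monitoring records behind such analyses are
rarely published, `cutox` ships first-class synthetic generators that
emulate them from the published design and summaries, so the whole chain
is reproducible and testable end to end.

## The models

**Probit dose–response.** Mortality by a fixed exposure time follows
`y_i ~ Binomial(n_i, Φ(α + β log10 c_i))`, fitted by Fisher scoring.
The median lethal concentration and its generalization are read off the
fitted line, `LCp = 10^((Φ⁻¹(p) − α)/β)`, with 95% CIs by the delta
method on log dose (default) or Fieller's theorem. Control mortality is
removed beforehand with Abbott's correction `(p − c)/(1 − c)`.

**LC50 decay with exposure time.** `LC50(t) = a·e^(−kt)`, fitted as OLS
of `ln LC50` on `t`; R² is reported on the log scale.

**Hardness normalization.** Hardness `H = 2.497·Ca + 4.118·Mg`
(mg CaCO3/L); the US EPA conversion `LC50(H_ref) = LC50·(H_ref/H)^0.9422`
brings LC50s measured at different hardness to a common reference
(50 mg CaCO3/L) for cross-study comparison.

**Copper partitioning.** `P·Cu = (T·Cu − D·Cu)/TSS` (mg Cu per mg
solid), `Kd = P·Cu/D·Cu`, and the empirical BLM-MONTE relation
`Kd = 1.04×10⁶·TSS^−0.7436`.

**Seasonal dm statistic.** For each variable,
`dm = (x̄_dry − ȳ_wet)/√(ES²_dry + ES²_wet)` with bootstrap standard
errors; `|dm| > 2` flags a seasonal difference.

## Worked example

Run the full chain on synthetic data generated under the study
conditions (seven Cu doses 0.05–1.42 mg/L, 10 fish per tank, 24–96 h,
true 96-h LC50 0.655 mg/L; monitoring series matched to the published
seasonal moments):

```sh
cutox -q pipeline --seed 42
```

```
Acute Cu toxicity report
========================
LC50 by exposure time (mg/L):
     24 h  0.982  [0.806, 1.197]
     48 h  0.802  [0.670, 0.960]
     72 h  0.709  [0.594, 0.847]
     96 h  0.638  [0.526, 0.774]
Decay fit: LC50(t) = 1.1007 * exp(-0.0059 t), R^2 = 0.9752 (log scale)
Test-water hardness: 308.7 mg CaCO3/L (Ca:Mg molar 1.46)
96-h LC50 0.638 mg/L -> 0.11 mg/L at reference hardness
Soft-water LC50 0.155 mg/L -> 0.12 mg/L
P.Cu 4.22e-05 mg/mg, Kd 0.0422, BLM-MONTE Kd 4.24e+03
Seasonal dm (dry vs wet, |dm| > 2 significant):
  Q_m3_s           dm =   -4.26 *
  pH               dm =   -0.35
  ...
```

Reading the output: the probit LC50 falls from ~1 mg/L at 24 h to
~0.64 mg/L at 96 h and the exponential fit recovers a decay rate near
the generating 0.0061 /h. The test water is very hard (309 mg CaCO3/L),
so the 96-h LC50 normalized to 50 mg CaCO3/L drops to ~0.12 mg/L —
matching the soft-water study on the same species after the same
normalization, which is the cross-study consistency the hardness model
predicts. Starred dm rows (discharge, TSS, major ions, total Cu) change
between seasons; pH, alkalinity, K and dissolved Cu do not.

The same stages are available individually (`cutox simulate`, `lc50`,
`decay`, `waterchem`, `seasonal`) and as library functions:

```python
from cutox import fit_probit, lc_p, fit_time_decay

fit = fit_probit(trial, time_h=96.0)      # trial: ToxicityTrial
est = lc_p(fit, 0.5)                      # LC50 with 95% CI
```

## Layout

- `cutox.dose_response` — probit fitting, LCp/CIs, Abbott correction, decay fit
- `cutox.water_chemistry` — hardness, normalization, Ca:Mg, partitioning
- `cutox.seasonal` — season classifier, bootstrap SEs, dm, summaries, hydrograph
- `cutox.synthetic` — trial and monitoring-series generators
- `cutox.pipeline` / `cutox.cli` — end-to-end runs, config, reports
- `cutox.datasets` — the published study inputs (dose grid, LC50 series,
  sampling-date chemistry, seasonal summary table)

See `docs/methods.md` for model details, defaults and limitations.
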