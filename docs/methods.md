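# Methods

`cutox` re-implements, as a tested library, the computational chain of an
acute copper-toxicity assessment in a strongly seasonal (dryland) river:
a 96-h static bioassay analysed by probit regression, an empirical
exponential decay of LC50 with exposure time, hardness normalization for
cross-study comparison, copper solid/solution partitioning, and a
bootstrap-based dry/wet-season comparison of the water chemistry that
modulates copper bioavailability.

## Probit dose–response and LCp

For one observation time, mortality in the tank at dose `c` is modelled as

    y_i ~ Binomial(n_i, Phi(alpha + beta * log10 c_i)),

the classical probit bioassay model. `fit_probit` maximises the binomial
likelihood by Fisher scoring (IRLS with the expected information),
starting from an empirical-probit least-squares line on shrunk mortality
fractions `(y + 0.5)/(n + 1)`. Convergence is declared when the
log-likelihood changes by less than 1e-8; the iteration cap is 100 and a
step is halved (up to 16-fold) whenever the full scoring step would reduce
the likelihood. Groups with 0% or 100% mortality stay in the likelihood —
the MLE handles them naturally; no ad-hoc 0.5/n corrections are applied.

Two degenerate regimes are handled explicitly rather than silently:

* **No information** (every fish dead, or none): `ValueError`.
* **Complete separation** (each group all-dead or all-alive, split
  monotone in dose): the slope MLE diverges. The fit is returned from a
  bounded grid search with `separation=True` and `converged=False`; LCp
  intervals are refused for such fits. A slope exceeding 75 probits per
  log10 unit triggers the same fallback.

The dose metameter is log10 (the convention of PROBIT programs);
`log_base` switches to natural log, which changes `alpha`, `beta` and the
covariance but — being a linear reparameterization — not the LCp point
estimates.

`lc_p` inverts the fitted line: `LCp = 10**((Phi^-1(p) - alpha)/beta)`.
The default 95% interval is the delta method on log10 dose (gradient
`(-1/beta, -m/beta)` against the inverse-information covariance); Fieller's
theorem is available as `method="fieller"`, falling back to a widened
delta interval when the Fieller set is unbounded (slope not significantly
positive). The interval construction used by the original study's
software is undocumented and its printed 24-h interval is irreproducibly
asymmetric, so the method label is carried in every output record.

Abbott's correction `(p - c)/(1 - c)` is applied per observation time
before fitting whenever the control shows mortality; corrected counts are
clipped to `[0, n]` and re-accumulated so they remain cumulative in time.
Zero control mortality returns the trial unchanged — the regime of the
reference dataset, where no control fish died.

## LC50 decay with exposure time

`fit_time_decay` fits `LC50(t) = a * exp(-k t)` by ordinary least squares
of `ln LC50` on `t` (at least 3 points, all positive). `R²` is reported on
the fitting (ln) scale; this reproduces the published coefficients
(a = 1.1428 mg/L, k = 0.0061 /h, R² = 0.9219) from the published LC50
quadruple to within input-rounding error. The log-linear fit weights all
points equally; no error-in-variables treatment is attempted since the
per-time LC50 standard errors are comparable.

## Hardness and normalization

Hardness is the CaCO3 equivalent of dissolved Ca and Mg,
`2.497 Ca + 4.118 Mg` (Standard Methods coefficients, exposed as module
constants). LC50s are moved between hardness levels with the US EPA
ambient-criteria conversion for copper,
`LC50(H_ref) = LC50 * (H_ref/H)**0.9422`, default reference 50 mg
CaCO3/L. The exponent is configurable; the transformation is strictly
decreasing in hardness and composes (H1→H2 then H2→H3 equals H1→H3),
both of which are property-tested. The Ca:Mg molar ratio uses atomic
masses 40.078 and 24.305.

## Copper partitioning

Particulate copper per unit solid is `P.Cu = (T.Cu - D.Cu)/TSS`, carried
internally in mg Cu per mg TSS with an explicit ug/g converter — the
reference dataset's tabulated P.Cu units are internally inconsistent
(its sampling-date entry equals `T.Cu - D.Cu` without the TSS division),
so the package is deliberately explicit about units rather than matching
that column. `Kd = P.Cu/D.Cu` is flagged `None` when dissolved copper is
zero instead of returning a silent 0. The empirical BLM-MONTE relation
`Kd = 1.04e6 * TSS**-0.7436` is provided for comparison; it is strictly
decreasing in TSS.

The Biotic Ligand Model itself (chemical speciation and gill-binding) is
out of scope: its binding constants are not part of this package's
inputs, and its prediction is treated as an external reference value.

## Seasonal comparison

Records are classified by calendar month: May–October dry, November–April
wet (configurable for other hydrological years). For each variable the
dm statistic

    dm = (x_bar_dry - y_bar_wet) / sqrt(ES_dry^2 + ES_wet^2),   |dm| > 2 => different

uses bootstrap standard errors: B resamples with replacement, each of the
observed size, SE = SD of the resampled means. Defaults: B = 2000 (the
source analysis does not state its B; 2000 makes the bootstrap noise in
dm well under 2% for the observed n), seed recorded in every result. The
same resampling seed is applied to both series so that
`dm(x, y) == -dm(y, x)` holds exactly, not just in distribution.

The source describes dm as computed on "standardized series" without
defining the standardization; dividing both series by a common pooled SD
cancels in the ratio, so the statistic is computed on raw series and an
optional `standardize` flag merely rescales the reported means/SEs.
Reconstructing dm from the published per-season (n, mean, std) with
SE = s/sqrt(n) reproduces the sign of all 15 published dm values and the
|dm| > 2 classification of all 15 (10 significant, 5 not); the numeric
values sit ~5–10% below the published ones uniformly, consistent with an
unstated detail of the original bootstrap that cannot be recovered from
the summaries.

Hydrograph summaries aggregate discharge by calendar month across years
(mean, 10th and 90th percentile, linear interpolation between order
statistics); empty months are omitted with a warning.

## Synthetic data

Raw per-tank mortality counts and raw monitoring records were never
published, so the generators emulate them from the published design and
summaries; generator defaults are the study conditions.

* **Trials** use the seven-dose grid (0.05–1.42 mg Cu/L), 10 fish per
  tank, observations at 24/48/72/96 h, and a generating probit with
  LC50(96 h) = 0.655 mg/L decaying at k = 0.0061 /h. The slope is not
  recoverable from the published summaries; the default of 4 probits per
  log10 dose is a moderately steep acute-metal response consistent with
  the published CI widths. Each fish carries a latent tolerance quantile
  `u ~ U(0,1)` and is dead by time t iff `u < P(death | c, t)`; because
  `P` is non-decreasing in t, cumulative counts are monotone pathwise
  (independent per-time binomials would violate this). Controls are
  death-free unless a background-mortality rate is set, in which case it
  mixes into all tanks as `p_obs = b + (1-b) p` — exactly the regime
  Abbott's correction removes.
* **Monitoring series** draw each variable/season independently from a
  lognormal matched to the published arithmetic mean and SD (lognormal
  because the variables are positive and right-skewed, e.g. TSS with
  mean 14760 and max 53960 mg/L in the wet season; only marginal
  summaries are published, so no cross-variable covariance is imposed).
  Sample sizes follow the published per-variable n (6–14); dates are
  placed mid-month in the matching season so the classifier round-trips.

What passing tests therefore show: the estimators recover known truths
under the assumed model (probit in log-dose, lognormal marginals,
independence). They do not establish robustness to real-data features the
generator omits: tank effects and within-tank correlation, dose
measurement error, cross-variable covariance in the chemistry, serial
dependence in the monitoring series, or non-lognormal tails.

## Verification sizes and numerical choices

Simulation-based checks use 500 replicate trials per true LC50
(0.2/0.4/0.655 mg/L) for parameter recovery and CI coverage, 20 random
trials against a brute-force grid-refinement likelihood maximizer
(parameter agreement to 1e-4), and 1000 replicate tanks for the
generator-calibration check (3 binomial SDs). Bootstrap-vs-analytic SE
agreement is checked at n = 100, B = 5000 within 5%. Probabilities are
clipped at 1e-10 inside IRLS weights and 1e-12 in likelihood evaluation;
the decay fit's R² is clamped to [0, 1] against floating-point spill.

## Known limitations

* The headline measured 96-h LC50 (0.655 mg/L) is not recomputable from
  published information (no raw counts); it enters as an input, and the
  package instead validates its probit machinery by oracle equivalence
  and parameter-recovery simulation.
* The delta/Fieller intervals are asymptotic; at n = 10 per tank they are
  mildly anti-conservative (observed coverage ≈ 0.93 at nominal 0.95).
* dm's |dm| > 2 rule is a fixed decision threshold, not a calibrated
  test; with n ≈ 10–14 per season its null exceedance is somewhat above
  the normal-theory 5%.
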