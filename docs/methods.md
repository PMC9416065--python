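# Methods

This note documents the statistical models implemented in `brainnorm`, the
generative model behind the synthetic cohorts, the parameters that matter,
and the limits of what the synthetic experiments demonstrate.

## Volume normalization and the log scale

Structure volumes are normalized for head size either proportionally
(`Vol / TotalVol`, the default; `TotalVol` is the sum of the brain, sulci
and cranial-space compartments) or by the residuals method
`Vol_adj = Vol − b(TotalVol − TotalVol_mean)` with `b` the OLS slope of
`Vol` on `TotalVol`. Relative volumes are carried internally as
dimensionless fractions; percentages appear only at reporting boundaries.
All modelling happens on the natural log of the fraction, which makes the
residual scatter approximately age-invariant (homoscedastic) and turns
multiplicative growth into additive change: a fitted log difference
`Δ = ŷ(60) − ŷ(30)` is reported as the percent change `100·(exp(Δ) − 1)`.
Natural log (not log10) is the package convention; it keeps the
thick-slice resolvability floor at ≈ −4.1 for a 1.67% fraction.

## Age trajectories and normative curves

Subject-level fits regress log relative volume on age with a 2nd-order
polynomial (order 3 optional; higher orders change the fits minimally and
are out of the default path). Reported per structure: R² of the fit, the
30→60-year percent change, and the size at 30 as percent of total volume.

Normative curves are built in two steps: per-integer-age windowed
statistics (a subject with floored age in `[a−2, a+2]` contributes to the
window at age `a`; ages 30–75), then separate unweighted OLS quadratic
fits of the window means and window sds, giving `V̄(age)` and
`V_std(age)`. Windows with fewer than 20 subjects are dropped before
fitting — edge ages thin out and destabilize the fit — and the calibration
builder relaxes this bar stepwise (10, 5, 2, 1, with a warning) for thin
sex-by-protocol strata rather than failing. The fitted sd curve is floored
at 1e−6; a fitted sd that goes non-positive anywhere falls back to a flat
sd at the mean window sd. Weighting window fits by n is available
(`weight_by_n=True`) but off by default.

Open choice: whether published trajectory tables pool sexes is not
determinable from summary tables alone; fits pool sexes by default with a
per-sex option, and normative/calibration curves are built and applied per
sex (the sexes differ visibly for CSF spaces).

## Cross-protocol calibration

Thicker slices inflate small CSF structures through partial-volume
effects. Under the assumption that populations scanned under different
protocols share one distribution, a value from a source protocol is mapped
to the reference (1.2 mm) protocol by age-conditional moment matching
(z-score preservation):

    V_cor = (V − V̄_src(age)) · V_std_ref(age)/V_std_src(age) + V̄_ref(age)

This is an algebraic identity on z-scores (preserved to 1e−12 in tests)
and is invertible given both curve pairs. Ages outside the fitted range
are clamped to the nearest fitted age with a warning; a strict mode
rejects them. Before pooling same-resolution data from different sites, a
one-way ANOVA gate requires the site main effect to be non-significant
(p > 0.05).

Variance decomposition uses a three-way ANOVA of log volume on protocol,
sex and decade of age (decades 20s–90s; empty decades are dropped), with
all interactions, Type II sums of squares (the conventional choice for
main-effect inference on unbalanced designs). Eta-squared is each term's
SS over the sum of all table SS (terms + residual); with Type II SS on
unbalanced data the components need not sum exactly to the corrected total
SS, so the table-sum denominator is used, which makes the shares sum to
100% by construction. Partial eta-squared is available as an option.

## Normative surface

z-scores are `(V − V̄(age))/V_std(age)` against the reference curves; the
population share above z is `100·(1 − Φ(z))` (15.9% at z = 1, 2.3% at
z = 2). Centile charts come from the normal model
(`V̄ + z_q·V_std`) and from gradient-boosted quantile regression with
pinball loss at fixed hyperparameters (50 estimators, depth 2, learning
rate 0.1, min leaf 50, min split 100). Boosting does not guarantee
non-crossing quantiles; crossings are resolved by sorting the curve values
per age. With only 50 shallow trees the boosted curves converge slowly at
the age extremes — on Gaussian data they agree with the normal model at
interior ages and diverge toward the edges, which is expected behaviour of
this fixed configuration, and the reason the tests compare the two models
only at interior ages. Flagging uses z > 2.0 by default. Quantile levels
default to the two-sided set {2.3, 15.9, 50, 84.1, 97.7}%, mirroring
z = ±1, ±2.

## Risk-factor association

Glucose, abdominal fat and blood pressure are log-transformed; weekly
alcohol frequency (0–7) stays linear. Subjects are binned per sex into the
40s/50s/60s decades. The volume response is the age residual
`V − V̄(age)` in log-volume units; dividing by `V_std(age)`
(`standardize=True`) is available but off by default because it rescales
slopes by 1/V_std and detaches them from the per-unit-factor scale on
which they are reported. Factors are linearly detrended against age within
each cell. Each cell fits a Huber M-estimator regression (statsmodels RLM,
HuberT with its standard tuning constant — "robust linear regression"
names a family; Huber is the default member) of the volume residual on the
factor plus protocol indicators and a repeat-scan indicator (repeat scans
enter as a 0/1 indicator; an ordinal coding is a trivial swap). The slope
p-value is the large-sample normal test. Because Huber fits have no
canonical R², both the full-model OLS R² and the factor-only OLS R² are
reported, labelled. Significance is flagged at 0.05 and at the Bonferroni
level 0.05/4 = 0.0125 (four factors). The full grid covers 4 factors × 2
sexes × 3 decades × 2 normalization variants = 48 cells; per-cell failures
are recorded without aborting the grid.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
images or segmentation:

- **Latent volumes.** Each subject carries one age-invariant residual per
  structure; the true log fraction at a scan is
  `m(age) + sex_term + residual`, with `m` quadratic in age. Repeat scans
  (probability 0.20, 1–2 years later) advance the same latent subject
  along the trajectory; extra within-subject longitudinal scatter is a
  config knob (`longitudinal_sd`, default 0 — the population trajectory is
  the only default source of longitudinal change, as the within-subject
  rate distribution is not identifiable from published summaries).
- **Trajectory presets.** For each of 13 structures, `c0, c1` are solved
  from the published size-at-30 and 30→60 change given a fixed curvature
  (+5e−5 /yr² for growing CSF spaces — expansion accelerates — and
  −5e−6 /yr² for shrinking tissue). The non-age variance is fixed by the
  published age-R² under the default age distribution (truncated normal,
  mean 52, sd 11, range 20–90, computed by quadrature), and split between
  a sex offset (15% of non-age variance for CSF spaces, 2% for tissue) and
  the between-subject residual sd. The sex term is centred at the
  reference sex mix (44% female) so the pooled curve equals `m(age)`
  exactly under the default demography. This is an analytic version of
  "calibrate the residual sd to hit the published R²": closed form, no
  simulation loop.
- **Observation model.** Protocols distort the observed log fraction
  affinely (`b0 + b1·v`), with gains < 1 anchored at log fraction −3.4 for
  thick slices, so the protocol gap shrinks as ventricles grow; extra
  log-scale noise; and an upward censoring floor (−4.1 for 2.5 mm,
  matching the resolvability bound of thick slices; −4.75 for 2.0 mm; none
  at 1.2 mm). Total volume and its compartments (Dirichlet-like fractions
  around brain 0.82 / sulci 0.06 / cranial 0.12 of a lognormal total,
  median 1.45 L, 10% log sd) are observed without protocol bias.
- **Clinical coupling.** Lognormal factors (glucose ~ log N(log 100,
  0.13²) mg/dl, fat ~ log N(log 90, 0.45²) cm², blood pressure ~
  log N(log 128, 0.11²) mmHg, with mild age drifts) are drawn conditionally
  on the subject's latent volume residual r with coupling
  `gamma = slope·var_t/var_r`, which preserves the factor's marginal
  variance and makes the regression of r on the factor recover the planted
  slope exactly in expectation. Weekly alcohol frequency uses a
  beta-binomial marginal (mean 2.0, sd 2.3 — drinking is bimodal, many
  abstainers and many daily drinkers) coupled through a Gaussian-copula
  quantile transform; the copula correlation is solved (with a quadrature
  factor for the discrete quantile map) so that `Cov(r, x)/Var(x)` equals
  the planted slope exactly. An additive propensity coupling would
  attenuate planted slopes ~20% through saturation at the bounded
  support's edges.
- **Planted-share ANOVA preset.** For the variance-decomposition
  experiments, the age-effect scale is set so its *between-decade*
  variance is 30.2% of total (what a decade-binned ANOVA attributes to
  age; the within-decade part of the trajectory goes to the residual), the
  sex offset plants 4.12%, and intercept-only protocol offsets at
  resolution-level mix weights (0.251/0.225/0.524) plant 1.15%.
- **Risk-recovery preset.** Single-sex, single-decade cohorts at the
  published cell sizes with intercept-only protocol offsets: gain
  distortion and censoring are what calibration removes upstream in the
  full pipeline, while the association regression handles intercept
  offsets with protocol dummies, so the recovery experiment isolates the
  regression machinery.

All generators are deterministic given the config seed (bit-identical
tables).

### What the synthetic experiments do and do not show

The generator matches first- and second-moment structure: trajectory
means, age-R², variance shares, planted regression slopes, the direction
and size-dependence of partial-volume bias, and repeat-scan structure. It
does **not** reproduce: heavy right tails and age-growing skewness of real
ventricular distributions (the log-normal residual is symmetric and
age-invariant — consequently the "resilience" fraction of sixties below
the thirties mean comes out near 3% rather than the ~11% real data show,
and flagged-outlier counts are exactly nominal); site effects beyond
protocol (the pooling gate is exercised under its null); real segmentation
failure modes; or medication/illness confounding of the clinical
measures. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to every real-data
pathology.

## Numerical choices

- Window boundaries use floored integer ages, inclusive `[a−2, a+2]`.
- Polynomial fits use `numpy.polynomial` least squares (ascending-power
  coefficients everywhere); rank-deficient designs raise.
- The sd curve is floored at 1e−6 at evaluation; degenerate sd fits fall
  back to a flat curve.
- Eta-squared uses the ANOVA-table SS sum as denominator (see above).
- Quantile-chart level crossings are sorted per age.
- Huber slope p-values use the normal approximation to the RLM z-statistic.
- The copula quantile factor is computed on a 20001-point grid over
  z ∈ [−8, 8] (error far below sampling noise).
- Problem sizes in the recovery experiments follow the published sample
  sizes where stated (5 000 trajectory subjects, 10 000 ANOVA subjects,
  4 224/4 279 risk-cell subjects); test-only simulations use smaller
  cohorts chosen to keep Monte-Carlo error well inside the asserted
  tolerances.

## Known limitations

- Calibration assumes identical underlying populations across protocols;
  with censored (floored) thick-slice data the moment match is
  approximate at young ages, where most censoring occurs.
- Curves are quadratic; real trajectories may need flexible fits near the
  age extremes (no spline/GAM alternatives are provided).
- The 505-structure segmentation hierarchy is out of scope; structure
  columns are treated generically and hemispheric splits are supported
  only as separate columns.
- The boosted quantile curves inherit the convergence behaviour of the
  fixed 50-tree configuration at edge ages; the normal model is the more
  robust estimate where data thin out.
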