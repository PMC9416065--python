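# brainnorm

Normative modelling of brain-structure volumes from heterogeneous
health-screening MRI.

Large screening programmes accumulate millions of brain MRI scans, but the
data are spread over sites and acquired with non-standardized, often
thick-slice protocols. `brainnorm` implements the statistical pipeline that
makes such data usable for quantifying age-related brain atrophy: head-size
normalization, log-scale age-trajectory fitting, cross-protocol calibration
by age-conditional moment matching, normative z-score/centile charts, and
robust regression of ventricular volume on modifiable dementia risk factors
(fasting glucose, blood pressure, abdominal fat, alcohol frequency). It is
aimed at researchers in imaging epidemiology and at anyone building
normative references from multi-protocol volumetric tables.

Because the underlying screening data are not public, the package ships a
first-class synthetic cohort generator whose presets reproduce the
published summary statistics (trajectory shapes, variance shares, risk
slopes), so every stage is testable end to end and every published number
can be re-derived as a parameter-recovery experiment.

## The model

Raw structure volumes are converted to relative volumes,
`Vol / TotalVol`, with `TotalVol` the total intracranial volume (brain +
sulci + cranial space); the alternative residuals method
`Vol_adj = Vol − b(TotalVol − TotalVol_mean)` is also provided. Relative
volumes are analysed in natural log, where the age trajectory of a
structure is modelled as a 2nd-order polynomial,

    V(age) ~ N( V̄(age), V_std(age)² ),   V̄, V_std quadratic in age,

estimated from windowed per-age statistics (±2-year windows, ages 30–75).
A value observed under protocol *p* (slice resolution 2.0 or 2.5 mm) is
calibrated to the 1.2 mm reference by matching age-conditional moments,

    V_cor = (V − V̄_p(age)) · V_std_ref(age)/V_std_p(age) + V̄_ref(age),

which preserves the within-protocol z-score exactly. Protocol, sex and
decade-of-age contributions to total variance are quantified by a
three-way ANOVA (eta² = SS_factor / SS_total). Individual scans get
z-scores `z = (V − V̄(age)) / V_std(age)`; centile charts come both from
this normal model and from gradient-boosted quantile regression (pinball
loss; 50 trees, depth 2, learning rate 0.1, leaf ≥ 50, split ≥ 100).
Risk-factor association uses Huber robust regression of the
age-residualized log ventricular volume on the (log-transformed where
appropriate) factor within sex × decade cells, with protocol and
repeat-scan indicators and Bonferroni control at 0.05/4.

## Worked example

```python
from brainnorm import synthetic, volumetry
from brainnorm.trajectories import fit_age_polynomial

presets = synthetic.default_presets()
config = synthetic.default_cohort_config(10000, seed=2024, identity_bias=True)
cohort = synthetic.generate_cohort(
    config, presets.trajectories, synthetic.identity_protocols()
)
first = volumetry.select_first_scan(cohort)
logv = volumetry.log_transform(volumetry.proportional_normalize(first, "ventricles"))
fit = fit_age_polynomial(logv, first["age"])
print(f"R^2 {fit.r_squared:.3f}, change {fit.change_30_60_percent:+.1f}%, "
      f"size at 30 {fit.size_at_30_percent:.2f}%")
```

prints

```
R^2 0.334, change +62.5%, size at 30 0.62%
```

— the ventricular volume fraction roughly at 0.6% of intracranial volume
at age 30, growing ~60% by age 60, with age explaining about a third of
the log-volume variance. The numbered drivers under `analysis/` walk the
full study: `01_simulate_cohort.py` (simulate volumes + clinical tables),
`02_age_trajectories.py` (the trajectory summary table above for all 13
structures), `03_protocol_effects.py` (site pooling, eta² decomposition —
age ≈ 30%, sex ≈ 4%, protocol ≈ 1.2% — and its collapse to ~0.002% after
calibration), `04_normative_charts.py` (centile charts, z > 2 flags ≈ 2%
of subjects) and `05_risk_factors.py` (the 48-cell association grid and
slope-recovery runs). Each writes its tables under `results/`.

There is also a CLI for running the pipeline on external tables:

```sh
brainnorm simulate --n 5000 --seed 1 --out-volumes vols.csv --out-clinical clin.csv
brainnorm run --volumes vols.csv --clinical clin.csv --out run1/
```

## Layout

    src/brainnorm/     library: synthetic, volumetry, trajectories,
                       harmonize, normative, risk, experiments, pipeline, cli
    analysis/          numbered narrative drivers (01–05)
    scripts/           acceptance.py
    tests/             pytest suite (unit, property and recovery tests)
    docs/methods.md    modelling assumptions, parameters and limitations
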