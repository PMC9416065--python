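"""Parameter-recovery experiments on synthetic cohorts.

The screening data behind the published summary statistics are not public,
so the reproducible quantities are recoveries: cohorts are generated with
trajectory / variance-share / risk-slope presets taken from the published
tables, the full analysis pipeline is run on them, and the recovered
quantities are compared with the planted (published) values.  These
experiment functions are shared by the test suite, the acceptance script
and the analysis drivers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from brainnorm import harmonize, risk, synthetic, volumetry
from brainnorm.trajectories import FitSummary, fit_age_polynomial

__all__ = [
    "trajectory_recovery",
    "anova_recovery",
    "calibration_recovery",
    "risk_slope_recovery",
    "seed_spread",
]

RECOVERY_STRUCTURES = ("ventricles", "cortex", "frontal_lobe")


def trajectory_recovery(
    seed: int,
    n_subjects: int = 5000,
    structures: tuple[str, ...] = RECOVERY_STRUCTURES,
) -> dict[str, FitSummary]:
    """Generate an identity-bias cohort and refit each structure's quadratic
    age trajectory from proportional log volumes (first scans only)."""
    presets = synthetic.default_presets()
    traj = {s: presets.trajectories[s] for s in structures}
    config = synthetic.default_cohort_config(
        n_subjects=n_subjects, seed=seed, identity_bias=True
    )
    cohort = synthetic.generate_cohort(config, traj, synthetic.identity_protocols())
    first = volumetry.select_first_scan(cohort)
    out = {}
    for s in structures:
        logv = volumetry.log_transform(volumetry.proportional_normalize(first, s))
        out[s] = fit_age_polynomial(logv, first["age"], structure=s)
    return out


def anova_recovery(
    seed: int, n_subjects: int = 10000
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Planted-share cohort -> three-way ANOVA before and after calibration.

    Returns (pre-calibration effect-size table, post-calibration table,
    post-calibration protocol p-value).
    """
    traj, protocols, config = synthetic.anova_preset(n_subjects, seed)
    cohort = synthetic.generate_cohort(config, {"ventricles": traj}, protocols)
    logv = volumetry.log_transform(
        volumetry.proportional_normalize(cohort, "ventricles")
    )
    df = cohort.assign(_logvol=np.asarray(logv, float))
    pre = harmonize.anova_effect_sizes(df, "_logvol")
    models = harmonize.build_calibration_models(
        df, df["_logvol"], reference_protocol="pooled-1.2", structure="ventricles"
    )
    post, p_protocol = harmonize.verify_calibration(df, models, df["_logvol"])
    return pre, post, p_protocol


def calibration_recovery(seed: int, n_subjects: int = 10000) -> dict[str, float]:
    """Headline numbers from anova_recovery as a flat dict."""
    pre, post, p = anova_recovery(seed, n_subjects)
    return {
        "eta2_age_percent": float(pre.loc["decade", "eta_squared_percent"]),
        "eta2_sex_percent": float(pre.loc["sex", "eta_squared_percent"]),
        "eta2_protocol_percent": float(pre.loc["protocol_id", "eta_squared_percent"]),
        "eta2_protocol_post_percent": float(
            post.loc["protocol_id", "eta_squared_percent"]
        ),
        "p_protocol_post": p,
    }


def risk_slope_recovery(
    factor: str,
    seed: int,
    n_subjects: int,
    *,
    sex: str = "M",
    decade: int = 50,
) -> risk.RiskRegressionResult:
    """Generate a single-sex single-decade cohort with one planted factor
    slope and recover it with the multivariate robust regression."""
    traj, protocols, config = synthetic.risk_cohort_preset(
        n_subjects, seed, sex=sex, decade=decade
    )
    cohort = synthetic.generate_cohort(config, traj, protocols)
    clinical = synthetic.generate_clinical(
        cohort, synthetic.default_risk_factors(), seed=seed + 1
    )
    logv = volumetry.log_transform(
        volumetry.proportional_normalize(cohort, "ventricles")
    )
    curves = risk._reference_curves(cohort, logv)
    designs = risk.prepare_regression_inputs(
        cohort, logv, clinical, curves, decades=(decade,)
    )
    return risk.robust_fit(
        designs[(sex, decade)], factor, sex=sex, decade=decade
    )


def seed_spread(fn, seeds, extract) -> tuple[np.ndarray, float, float]:
    """Run an experiment over several seeds; return (values, mean, sd)."""
    vals = np.array([extract(fn(int(s))) for s in seeds], float)
    return vals, float(vals.mean()), float(vals.std(ddof=1))
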