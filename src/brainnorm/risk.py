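"""Association of ventricular volume with modifiable risk factors.

Reproduces the screening-study procedure: calibrated, pooled log
ventricular volumes are residualized against age using the normative
curves; glucose, abdominal fat and blood pressure are log-transformed
(alcohol frequency stays linear); subjects are binned into the 40s/50s/60s
decades per sex; within each cell a multivariate robust (Huber) linear
regression of the volume residual on the factor plus protocol indicators
and a repeat-scan indicator yields the slope and its p-value, flagged at
0.05 and at the Bonferroni level 0.05/4 = 0.0125.  The full grid runs both
head-size normalization variants (proportional and residuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from brainnorm import volumetry
from brainnorm.trajectories import (
    AgeVolumeCurve,
    fit_curves,
    windowed_age_stats,
)
from brainnorm.volumetry import decade_of

__all__ = [
    "FACTOR_COLUMNS",
    "LOG_FACTORS",
    "RiskRegressionResult",
    "prepare_regression_inputs",
    "robust_fit",
    "run_table3",
    "binned_effect_plot",
]

# canonical clinical-table columns per factor
FACTOR_COLUMNS = {
    "glucose": "glucose_mg_dl",
    "abdominal_fat": "abdominal_fat_cm2",
    "blood_pressure": "blood_pressure_max_mmhg",
    "alcohol_frequency": "alcohol_per_week",
}
# factors analysed on the natural-log scale (alcohol counts stay linear)
LOG_FACTORS = ("glucose", "abdominal_fat", "blood_pressure")

DEFAULT_DECADES = (40, 50, 60)
BONFERRONI_DIVISOR = 4
ALPHA = 0.05


@dataclass(frozen=True)
class RiskRegressionResult:
    factor: str
    sex: str
    decade: int
    n: int
    slope: float
    slope_se: float
    p_value: float
    r_squared: float  # full-model OLS R^2 on the same design
    r_squared_factor: float  # factor-only OLS R^2
    significant_at_005: bool
    significant_at_bonferroni: bool
    normalization: str = "proportional"
    error: str = ""

    def __post_init__(self) -> None:
        if self.error:
            return
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.significant_at_bonferroni and not self.significant_at_005:
            raise ValueError("Bonferroni significance implies 0.05 significance")

    def to_dict(self) -> dict:
        return asdict(self)


def _detrend_on_age(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Remove the within-cell linear age trend (intercept included)."""
    if np.ptp(ages) == 0:
        return values - values.mean()
    coef = np.polyfit(ages, values, 1)
    return values - np.polyval(coef, ages)


def prepare_regression_inputs(
    volumes: pd.DataFrame,
    log_volume: pd.Series,
    clinical: pd.DataFrame,
    curves: dict[str, AgeVolumeCurve],
    *,
    decades: tuple[int, ...] = DEFAULT_DECADES,
    standardize: bool = False,
    detrend_factors: bool = True,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Build one design table per (sex, decade) cell.

    ``log_volume`` is the calibrated pooled log volume aligned with
    ``volumes``; ``curves`` maps sex to its reference age-volume curve.
    The volume covariate is the age residual V - Vbar(age) in log-volume
    units (divided by Vstd(age) when ``standardize``); factors are
    log-transformed where applicable and linearly detrended against age
    within the cell.
    """
    missing = [c for c in FACTOR_COLUMNS.values() if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table is missing columns: {missing}")
    df = volumes.copy()
    df["_logvol"] = np.asarray(log_volume, float)
    df = df.merge(
        clinical.drop(columns=[c for c in ("age", "sex") if c in clinical.columns]),
        on="subject_id",
        how="inner",
    )
    df["decade"] = decade_of(df["age"])
    df["repeat_scan"] = (df["scan_ordinal"] > 1).astype(int)

    out: dict[tuple[str, int], pd.DataFrame] = {}
    for sex, curve in curves.items():
        for dec in decades:
            cell = df[(df["sex"] == sex) & (df["decade"] == dec)].copy()
            if cell.empty:
                continue
            ages = cell["age"].to_numpy()
            resid = cell["_logvol"].to_numpy() - curve.mean(ages)
            if standardize:
                resid = resid / curve.std(ages)
            cell["vol_resid"] = resid
            for factor, col in FACTOR_COLUMNS.items():
                vals = cell[col].to_numpy(float)
                if factor in LOG_FACTORS:
                    if np.any(vals <= 0):
                        raise ValueError(f"{col}: log transform needs positive values")
                    vals = np.log(vals)
                if detrend_factors:
                    vals = _detrend_on_age(vals, ages)
                cell[factor] = vals
            keep = [
                "subject_id",
                "age",
                "sex",
                "protocol_id",
                "scan_ordinal",
                "repeat_scan",
                "vol_resid",
                *FACTOR_COLUMNS,
            ]
            out[(sex, dec)] = cell[keep].reset_index(drop=True)
    return out


def _design_matrix(design: pd.DataFrame, factor: str) -> pd.DataFrame:
    X = pd.DataFrame({factor: design[factor].to_numpy(float)}, index=design.index)
    protos = sorted(design["protocol_id"].unique())
    for p in protos[1:]:  # first protocol is the baseline
        X[f"protocol[{p}]"] = (design["protocol_id"] == p).astype(float)
    if design["repeat_scan"].nunique() > 1:
        X["repeat_scan"] = design["repeat_scan"].to_numpy(float)
    return sm.add_constant(X)


def robust_fit(
    design: pd.DataFrame,
    factor: str,
    *,
    sex: str = "",
    decade: int = 0,
    normalization: str = "proportional",
    alpha: float = ALPHA,
    bonferroni_divisor: int = BONFERRONI_DIVISOR,
) -> RiskRegressionResult:
    """Huber M-estimator regression of the volume residual on one factor.

    Covariates: protocol indicators and a repeat-scan indicator.  The
    p-value is the large-sample normal test on the factor slope.  Both the
    full-model OLS R^2 and the factor-only OLS R^2 are reported.
    """
    if factor not in design.columns:
        raise KeyError(f"factor {factor!r} not in design")
    if len(design) < 30:
        raise ValueError(f"cell too small for a stable fit (n={len(design)})")
    y = design["vol_resid"].to_numpy(float)
    X = _design_matrix(design, factor)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
    slope = float(rlm.params[factor])
    se = float(rlm.bse[factor])
    from scipy import stats as sps

    p = float(2.0 * sps.norm.sf(abs(slope / se))) if se > 0 else float("nan")
    ols_full = sm.OLS(y, X).fit()
    ols_factor = sm.OLS(y, sm.add_constant(design[[factor]].to_numpy(float))).fit()
    bonf = p < alpha / bonferroni_divisor
    return RiskRegressionResult(
        factor=factor,
        sex=sex,
        decade=decade,
        n=int(len(design)),
        slope=slope,
        slope_se=se,
        p_value=p,
        r_squared=float(ols_full.rsquared),
        r_squared_factor=float(ols_factor.rsquared),
        significant_at_005=bool(p < alpha),
        significant_at_bonferroni=bool(bonf),
        normalization=normalization,
    )


def _reference_curves(
    volumes: pd.DataFrame, log_volume: pd.Series, *, min_count: int = 20
) -> dict[str, AgeVolumeCurve]:
    """Per-sex 2nd-order mean/sd curves from first scans of pooled data."""
    first = volumetry.select_first_scan(
        volumes.assign(_logvol=np.asarray(log_volume, float))
    )
    curves = {}
    for sex, sub in first.groupby("sex"):
        stats_ = windowed_age_stats(sub["_logvol"], sub["age"])
        curves[str(sex)] = fit_curves(stats_, sex=str(sex), min_count=min_count)
    return curves


def run_table3(
    volumes: pd.DataFrame,
    clinical: pd.DataFrame,
    *,
    structure: str = "ventricles",
    log_volume_by_variant: dict[str, pd.Series] | None = None,
    decades: tuple[int, ...] = DEFAULT_DECADES,
    factors: tuple[str, ...] = tuple(FACTOR_COLUMNS),
    min_window_count: int = 20,
) -> pd.DataFrame:
    """Full association grid: factors x sexes x decades x normalizations.

    By default the two normalization variants are computed from the raw
    table (proportional fractions and residuals-method adjusted volumes,
    both in natural log); pre-calibrated series may be supplied instead via
    ``log_volume_by_variant``.  Per-cell failures are recorded in the
    ``error`` column without aborting the grid.
    """
    if log_volume_by_variant is None:
        frac = volumetry.proportional_normalize(volumes, structure)
        model = volumetry.fit_residual_model(
            volumetry.select_first_scan(volumes), structure
        )
        adj = volumetry.residual_adjust(volumes, model)
        if (adj <= 0).any():
            warnings.warn("dropping rows with non-positive adjusted volumes")
        log_volume_by_variant = {
            "proportional": volumetry.log_transform(frac),
            "residuals": np.log(adj.where(adj > 0)),
        }
    rows = []
    for variant, logvol in log_volume_by_variant.items():
        mask = pd.Series(np.asarray(logvol, float), index=volumes.index).notna()
        vols = volumes[mask]
        lv = pd.Series(np.asarray(logvol, float), index=volumes.index)[mask]
        curves = _reference_curves(vols, lv, min_count=min_window_count)
        designs = prepare_regression_inputs(
            vols, lv, clinical, curves, decades=decades
        )
        for sex in sorted(curves):
            for dec in decades:
                design = designs.get((sex, dec))
                for factor in factors:
                    if design is None:
                        rows.append(
                            RiskRegressionResult(
                                factor, sex, dec, 0, *(float("nan"),) * 5,
                                False, False, variant, "empty cell",
                            ).to_dict()
                        )
                        continue
                    try:
                        rows.append(
                            robust_fit(
                                design,
                                factor,
                                sex=sex,
                                decade=dec,
                                normalization=variant,
                            ).to_dict()
                        )
                    except Exception as exc:  # keep the grid going
                        rows.append(
                            RiskRegressionResult(
                                factor, sex, dec, len(design),
                                *(float("nan"),) * 5,
                                False, False, variant, str(exc),
                            ).to_dict()
                        )
    return pd.DataFrame(rows)


def binned_effect_plot(
    design: pd.DataFrame,
    factor: str,
    bin_edges,
) -> pd.DataFrame:
    """Mean volume residual, standard error and n per factor bin."""
    edges = np.asarray(bin_edges, float)
    if edges.size < 2:
        raise ValueError("need at least two bin edges")
    x = design[factor].to_numpy(float)
    y = design["vol_resid"].to_numpy(float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (x >= lo) & (x < hi)
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"empty bin [{lo}, {hi}) dropped")
            continue
        vals = y[sel]
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append((lo, hi, float(vals.mean()), se, n))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "mean", "se", "n"])
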