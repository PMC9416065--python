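"""Population-distribution characterization of brain atrophy.

Given calibrated, pooled log relative volumes and a reference age-volume
curve, this module builds the normative surface: per-decade histograms with
normal fits, individual z-scores z = (V - Vbar(age)) / Vstd(age), tail
percentages 100*(1 - Phi(z)), centile charts from both the normal model and
gradient-boosted quantile regression (pinball loss), outlier flagging at a
z threshold, and the fraction of an older decade whose volumes undercut a
younger decade's mean ("resilience").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

from brainnorm.trajectories import AgeVolumeCurve
from brainnorm.volumetry import decade_of

__all__ = [
    "NormativeModel",
    "QuantileChart",
    "GBR_PARAMS",
    "DEFAULT_QUANTILE_LEVELS",
    "decade_histograms",
    "z_score",
    "z_to_upper_tail_percent",
    "boosted_quantile_chart",
    "flag_large_ventricles",
    "resilience_fraction",
]

# two-sided levels mirroring z = -2, -1, 0, +1, +2
DEFAULT_QUANTILE_LEVELS = (0.023, 0.159, 0.5, 0.841, 0.977)

# gradient-boosting hyperparameters for quantile charts
GBR_PARAMS = dict(
    n_estimators=50,
    max_depth=2,
    learning_rate=0.1,
    min_samples_leaf=50,
    min_samples_split=100,
)


@dataclass(frozen=True)
class NormativeModel:
    """Reference curve plus a z threshold for flagging large ventricles."""

    curve: AgeVolumeCurve
    z_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


def z_score(values, ages, model: NormativeModel, *, clamp_ages: bool = True):
    """z = (V - Vbar(age)) / Vstd(age) under the reference curve."""
    values = np.asarray(values, float)
    ages = np.asarray(ages, float)
    if not clamp_ages:
        lo, hi = model.curve.age_range
        if np.any((ages < lo) | (ages > hi)):
            raise ValueError(f"age outside the normative range [{lo}, {hi}]")
    c = model.curve
    return (values - c.mean(ages, clamp=clamp_ages)) / c.std(ages, clamp=clamp_ages)


def z_to_upper_tail_percent(z):
    """Percent of the population exceeding a given z: 100*(1 - Phi(z))."""
    return 100.0 * stats.norm.sf(np.asarray(z, float))


def decade_histograms(
    table: pd.DataFrame,
    values: pd.Series,
    *,
    bins: int = 30,
    log_input: bool = True,
) -> dict[int, dict]:
    """Per-decade histograms and normal fits, on linear and log scales.

    ``values`` are log relative volumes when ``log_input`` (the default);
    linear-scale statistics are computed on exp(values).  Reports per
    decade: counts and bin edges (log scale), fitted (mean, sd) in log
    scale, and skewness on both scales.
    """
    log_vals = np.asarray(values, float) if log_input else np.log(np.asarray(values, float))
    decades = decade_of(table["age"]).to_numpy()
    out: dict[int, dict] = {}
    for dec in sorted(np.unique(decades)):
        v = log_vals[decades == dec]
        counts, edges = np.histogram(v, bins=bins)
        out[int(dec)] = {
            "n": int(v.size),
            "counts": counts.tolist(),
            "bin_edges": edges.tolist(),
            "mean_log": float(v.mean()),
            "sd_log": float(v.std(ddof=0)),
            "skew_log": float(stats.skew(v)) if v.size > 2 else float("nan"),
            "skew_linear": float(stats.skew(np.exp(v))) if v.size > 2 else float("nan"),
        }
    return out


@dataclass(frozen=True)
class QuantileChart:
    """Age-resolved centile curves from the normal model and from boosting."""

    structure: str
    sex: str
    levels: tuple[float, ...]
    ages: tuple[int, ...]
    normal_curves: dict[float, tuple[float, ...]] = field(default_factory=dict)
    boosted_curves: dict[float, tuple[float, ...]] = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["normal_curves"] = {str(k): list(v) for k, v in self.normal_curves.items()}
        d["boosted_curves"] = {str(k): list(v) for k, v in self.boosted_curves.items()}
        Path(path).write_text(json.dumps(d, indent=2))


def _sort_across_levels(
    curves: dict[float, np.ndarray], levels: tuple[float, ...]
) -> dict[float, np.ndarray]:
    """Enforce level-monotonicity per age by sorting crossed curve values."""
    mat = np.vstack([curves[lv] for lv in levels])
    order = np.argsort(list(levels))
    mat_sorted = np.sort(mat[order], axis=0)
    out = {}
    for rank, idx in enumerate(order):
        out[levels[idx]] = mat_sorted[rank]
    return out


def boosted_quantile_chart(
    log_volumes,
    ages,
    levels: tuple[float, ...] = DEFAULT_QUANTILE_LEVELS,
    *,
    curve: AgeVolumeCurve | None = None,
    age_grid: np.ndarray | None = None,
    structure: str = "",
    sex: str = "all",
    random_state: int = 0,
) -> QuantileChart:
    """Centile curves by gradient boosting with pinball loss.

    One regressor per level with the fixed hyperparameters in
    ``GBR_PARAMS``.  If a reference curve is supplied, the matching
    normal-model centiles Vbar(age) + z_q * Vstd(age) are included.
    Crossing curves are resolved by per-age sorting.
    """
    y = np.asarray(log_volumes, float)
    a = np.asarray(ages, float)
    if y.size < GBR_PARAMS["min_samples_split"]:
        raise ValueError(
            f"need at least {GBR_PARAMS['min_samples_split']} points for boosting"
        )
    if age_grid is None:
        lo, hi = (curve.age_range if curve is not None else (int(a.min()), int(a.max())))
        age_grid = np.arange(lo, hi + 1)
    age_grid = np.asarray(age_grid)

    boosted: dict[float, np.ndarray] = {}
    X = a.reshape(-1, 1)
    for lv in levels:
        gbr = GradientBoostingRegressor(
            loss="quantile", alpha=lv, random_state=random_state, **GBR_PARAMS
        )
        gbr.fit(X, y)
        boosted[lv] = gbr.predict(age_grid.reshape(-1, 1).astype(float))
    boosted = _sort_across_levels(boosted, tuple(levels))

    normal: dict[float, np.ndarray] = {}
    if curve is not None:
        for lv in levels:
            zq = stats.norm.ppf(lv)
            normal[lv] = curve.mean(age_grid) + zq * curve.std(age_grid)
        normal = _sort_across_levels(normal, tuple(levels))

    return QuantileChart(
        structure=structure,
        sex=sex,
        levels=tuple(levels),
        ages=tuple(int(x) for x in age_grid),
        normal_curves={lv: tuple(map(float, v)) for lv, v in normal.items()},
        boosted_curves={lv: tuple(map(float, v)) for lv, v in boosted.items()},
        hyperparameters=dict(GBR_PARAMS),
    )


def flag_large_ventricles(
    table: pd.DataFrame,
    values,
    model: NormativeModel,
) -> pd.DataFrame:
    """Rows whose z-score exceeds the model threshold (default z > 2)."""
    z = z_score(values, table["age"].to_numpy(), model)
    flagged = table.loc[z > model.z_threshold, :].copy()
    flagged["z"] = z[z > model.z_threshold]
    keep = [
        c
        for c in ("subject_id", "scan_id", "age", "sex", "protocol_id", "z")
        if c in flagged.columns
    ]
    return flagged[keep].reset_index(drop=True)


def resilience_fraction(
    table: pd.DataFrame,
    values: pd.Series,
    young_decade: int = 30,
    old_decade: int = 60,
) -> float:
    """Percent of the old decade whose log volumes lie below the young
    decade's mean (subjects whose anatomy 'stayed young')."""
    decades = decade_of(table["age"]).to_numpy()
    vals = np.asarray(values, float)
    young = vals[decades == young_decade]
    old = vals[decades == old_decade]
    if young.size == 0 or old.size == 0:
        raise ValueError("both decades must be non-empty")
    return 100.0 * float(np.mean(old < young.mean()))
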