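"""Age-trajectory fitting for log relative volumes.

Two layers: a subject-level polynomial regression of log volume on age
(reporting R^2, the 30->60-year percent change and the size at 30), and the
normative layer that computes windowed per-age mean/sd statistics and fits
2nd-order polynomial curves V(age) (mean) and V_std(age) for one
(structure, sex, protocol) scope.  The curves are the substrate for
cross-protocol calibration and z-scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FitSummary",
    "AgeVolumeCurve",
    "fit_age_polynomial",
    "windowed_age_stats",
    "fit_curves",
    "DEFAULT_AGE_RANGE",
    "DEFAULT_MIN_WINDOW_COUNT",
]

DEFAULT_AGE_RANGE = (30, 75)
DEFAULT_HALF_WIDTH = 2
DEFAULT_MIN_WINDOW_COUNT = 20
_STD_FLOOR = 1e-6


def _polyval(coef: np.ndarray, age) -> np.ndarray:
    """Evaluate ascending-power coefficients at age."""
    return np.polynomial.polynomial.polyval(np.asarray(age, float), coef)


@dataclass(frozen=True)
class FitSummary:
    """Summary of a polynomial fit of log relative volume on age."""

    structure: str
    sex: str  # "F", "M" or "all"
    order: int
    coefficients: tuple[float, ...]  # ascending powers
    r_squared: float
    change_30_60_percent: float
    size_at_30_percent: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.order not in (2, 3):
            raise ValueError("polynomial order must be 2 or 3")

    def predict(self, age):
        return _polyval(np.asarray(self.coefficients), age)

    def to_dict(self) -> dict:
        return asdict(self)


def fit_age_polynomial(
    log_volumes,
    ages,
    order: int = 2,
    *,
    structure: str = "",
    sex: str = "all",
) -> FitSummary:
    """Least-squares polynomial fit of log relative volume on age.

    The percent change between 30 and 60 is computed on the log fit and
    exponentiated, 100*(exp(yhat(60)-yhat(30))-1); the size at 30 is
    100*exp(yhat(30)) (percent of total volume).
    """
    y = np.asarray(log_volumes, float)
    a = np.asarray(ages, float)
    if y.shape != a.shape:
        raise ValueError("log_volumes and ages must have equal length")
    if y.size < order + 2:
        raise ValueError(f"need at least {order + 2} points for an order-{order} fit")
    if np.ptp(a) == 0:
        raise np.linalg.LinAlgError("design is rank deficient: constant ages")
    coef = np.polynomial.polynomial.polyfit(a, y, order)
    yhat = _polyval(coef, a)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    y30, y60 = float(_polyval(coef, 30.0)), float(_polyval(coef, 60.0))
    return FitSummary(
        structure=structure,
        sex=sex,
        order=order,
        coefficients=tuple(float(c) for c in coef),
        r_squared=min(r2, 1.0),
        change_30_60_percent=100.0 * float(np.expm1(y60 - y30)),
        size_at_30_percent=100.0 * float(np.exp(y30)),
        n=int(y.size),
    )


def windowed_age_stats(
    log_volumes,
    ages,
    half_width: int = DEFAULT_HALF_WIDTH,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
) -> pd.DataFrame:
    """Per-integer-age mean/sd/n over a +/- half_width-year window.

    Ages are floored to integer years; a subject with floored age in
    [a - half_width, a + half_width] contributes to the window at age a.
    Returns a frame with columns age, mean, sd, n (sd is 0 for n == 1,
    NaN stats for empty windows).
    """
    y = np.asarray(log_volumes, float)
    a = np.floor(np.asarray(ages, float)).astype(int)
    if y.size == 0:
        raise ValueError("empty input")
    lo, hi = age_range
    rows = []
    for center in range(lo, hi + 1):
        sel = (a >= center - half_width) & (a <= center + half_width)
        n = int(sel.sum())
        if n == 0:
            rows.append((center, np.nan, np.nan, 0))
        else:
            vals = y[sel]
            rows.append((center, float(vals.mean()), float(vals.std(ddof=0)), n))
    out = pd.DataFrame(rows, columns=["age", "mean", "sd", "n"])
    if (out["n"] == 0).all():
        raise ValueError(f"no data in the age range {age_range}")
    return out


@dataclass(frozen=True)
class AgeVolumeCurve:
    """2nd-order polynomial mean and sd of log relative volume vs age."""

    structure: str
    sex: str
    protocol_id: str
    age_range: tuple[int, int]
    mean_coefficients: tuple[float, ...]  # ascending powers
    std_coefficients: tuple[float, ...]
    window_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        ages = np.arange(lo, hi + 1)
        if np.any(self.std(ages, clamp=False) <= 0):
            raise ValueError("std curve must be positive over the age range")

    def _clamped(self, age, clamp: bool):
        age = np.asarray(age, dtype=float)
        lo, hi = self.age_range
        if clamp:
            out = (age < lo) | (age > hi)
            if np.any(out):
                warnings.warn(
                    f"{int(np.sum(out))} age(s) outside [{lo}, {hi}] clamped to range",
                    stacklevel=3,
                )
            age = np.clip(age, lo, hi)
        return age

    def mean(self, age, clamp: bool = True):
        return _polyval(np.asarray(self.mean_coefficients), self._clamped(age, clamp))

    def std(self, age, clamp: bool = True):
        raw = _polyval(np.asarray(self.std_coefficients), self._clamped(age, clamp))
        return np.maximum(raw, _STD_FLOOR)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_counts"] = {str(k): v for k, v in self.window_counts.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AgeVolumeCurve":
        return cls(
            structure=d["structure"],
            sex=d["sex"],
            protocol_id=d["protocol_id"],
            age_range=tuple(d["age_range"]),
            mean_coefficients=tuple(d["mean_coefficients"]),
            std_coefficients=tuple(d["std_coefficients"]),
            window_counts={int(k): v for k, v in d.get("window_counts", {}).items()},
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AgeVolumeCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_curves(
    window_stats: pd.DataFrame,
    order: int = 2,
    *,
    structure: str = "",
    sex: str = "all",
    protocol_id: str = "",
    min_count: int = DEFAULT_MIN_WINDOW_COUNT,
    weight_by_n: bool = False,
) -> AgeVolumeCurve:
    """Fit mean and sd polynomial curves to windowed age statistics.

    Windows with fewer than ``min_count`` subjects are dropped before
    fitting (edge ages are unstable as the sample thins out); the sd curve
    is floored at a small positive epsilon at evaluation time.
    """
    kept = window_stats[window_stats["n"] >= max(min_count, 1)]
    if len(kept) < order + 2:
        raise ValueError(
            f"only {len(kept)} windows with n >= {min_count}; cannot fit order {order}"
        )
    ages = kept["age"].to_numpy(float)
    w = kept["n"].to_numpy(float) if weight_by_n else None
    mean_coef = np.polynomial.polynomial.polyfit(ages, kept["mean"].to_numpy(), order, w=w)
    std_coef = np.polynomial.polynomial.polyfit(ages, kept["sd"].to_numpy(), order, w=w)
    lo, hi = int(kept["age"].min()), int(kept["age"].max())
    # keep the declared range but guard against a non-positive fitted sd
    grid = np.arange(lo, hi + 1)
    sd_fit = np.polynomial.polynomial.polyval(grid.astype(float), std_coef)
    if np.any(sd_fit <= 0):
        std_coef = np.array([max(float(kept["sd"].mean()), _STD_FLOOR), 0.0, 0.0][: order + 1])
    return AgeVolumeCurve(
        structure=structure,
        sex=sex,
        protocol_id=protocol_id,
        age_range=(lo, hi),
        mean_coefficients=tuple(float(c) for c in mean_coef),
        std_coefficients=tuple(float(c) for c in std_coef),
        window_counts={int(a): int(n) for a, n in zip(kept["age"], kept["n"])},
    )
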