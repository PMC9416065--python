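"""Synthetic screening-cohort generator.

Emulates the statistical structure of large health-checkup brain-volumetry
data: lognormal structure volumes whose log relative volume follows a
quadratic age trajectory with a sex offset and age-invariant between-subject
scatter; scanner-protocol measurement bias that is affine in log volume and
shrinks as structures grow (partial-volume behaviour), with an optional
detection floor for thick-slice protocols; repeated scans that advance the
same latent subject along its trajectory; and clinical risk factors coupled
to the age-residualized log ventricular volume with plantable slopes.

Every generator is deterministic given the seed carried by its config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeDistribution",
    "TrajectorySpec",
    "ProtocolBiasSpec",
    "RiskFactorSpec",
    "CohortConfig",
    "default_presets",
    "identity_protocols",
    "default_cohort_config",
    "anova_preset",
    "risk_cohort_preset",
    "generate_cohort",
    "generate_clinical",
    "TABLE_STRUCTURES",
]

LOG_TOTAL_VOLUME_MEAN = math.log(1.45e6)  # mm^3, adult intracranial space
LOG_TOTAL_VOLUME_SD = 0.10
COMPARTMENTS = ("brain", "sulci", "cranial_space")
COMPARTMENT_BASE = np.array([0.82, 0.06, 0.12])
COMPARTMENT_CONCENTRATION = 400.0


# --------------------------------------------------------------------------- #
# age distribution


@dataclass(frozen=True)
class AgeDistribution:
    """Truncated-normal age distribution (years)."""

    mean: float = 52.0
    sd: float = 11.0
    low: float = 20.0
    high: float = 90.0

    def __post_init__(self) -> None:
        if not (20.0 <= self.low < self.high <= 90.0):
            raise ValueError("age range must satisfy 20 <= low < high <= 90")
        if self.sd <= 0:
            raise ValueError("age sd must be positive")

    def _frozen(self) -> stats.rv_continuous:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)

    def grid(self, step: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature grid (ages, normalized weights) over the support."""
        ages = np.arange(self.low + step / 2, self.high, step)
        w = self._frozen().pdf(ages)
        return ages, w / w.sum()


# --------------------------------------------------------------------------- #
# specs


@dataclass(frozen=True)
class TrajectorySpec:
    """Quadratic mean trajectory of log relative volume vs age.

    mean(age) = c0 + c1*age + c2*age**2, natural log of the dimensionless
    volume fraction.  ``sex_offset`` is the male-minus-female gap in log
    volume, centred at ``male_fraction_ref`` so that the pooled population
    mean equals the trajectory at the reference sex mix.  ``residual_sd``
    is the age-invariant between-subject sd of log relative volume.
    """

    structure: str
    c0: float
    c1: float
    c2: float
    sex_offset: float = 0.0
    residual_sd: float = 0.15
    male_fraction_ref: float = 0.5  # male fraction at which the pooled curve is centred

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError(f"{self.structure}: residual_sd must be > 0")
        ages = np.linspace(20.0, 90.0, 141)
        m = self.mean_log_frac(ages)
        if not np.all((m > -12.0) & (m < 0.0)):
            raise ValueError(
                f"{self.structure}: mean log fraction leaves (-12, 0) on ages 20-90"
            )

    def mean_log_frac(self, age):
        age = np.asarray(age, dtype=float)
        return self.c0 + self.c1 * age + self.c2 * age * age

    def change_30_60_percent(self) -> float:
        return 100.0 * math.expm1(
            float(self.mean_log_frac(60.0) - self.mean_log_frac(30.0))
        )

    def size_at_30_percent(self) -> float:
        return 100.0 * math.exp(float(self.mean_log_frac(30.0)))


@dataclass(frozen=True)
class ProtocolBiasSpec:
    """Affine measurement distortion of observed log relative volume.

    observed = bias_intercept + bias_slope * true + N(0, extra_noise_sd),
    then censored upward at ``floor_log`` (thick-slice protocols cannot
    resolve structures below a partial-volume floor).
    """

    protocol_id: str
    site: str
    slice_resolution_mm: float
    bias_intercept: float = 0.0
    bias_slope: float = 1.0
    extra_noise_sd: float = 0.0
    floor_log: float = -np.inf

    def __post_init__(self) -> None:
        if self.slice_resolution_mm not in (1.2, 2.0, 2.5):
            raise ValueError("slice_resolution_mm must be one of 1.2, 2.0, 2.5")
        if self.extra_noise_sd < 0:
            raise ValueError("extra_noise_sd must be >= 0")
        if np.isfinite(self.floor_log) and self.slice_resolution_mm <= 1.2:
            raise ValueError("finite floor_log only allowed for resolutions > 1.2 mm")

    def observe(self, true_log: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        obs = self.bias_intercept + self.bias_slope * np.asarray(true_log, float)
        if self.extra_noise_sd > 0:
            obs = obs + rng.normal(0.0, self.extra_noise_sd, size=obs.shape)
        return np.maximum(obs, self.floor_log)


@dataclass(frozen=True)
class RiskFactorSpec:
    """A clinical/lifestyle factor coupled to ventricular volume.

    ``kind`` is "lognormal" (baseline mean/sd on the natural-log scale,
    values emitted on the raw measurement scale) or "count7" (weekly count
    in 0..7 generated as a beta-binomial: a per-subject propensity drawn
    from a Beta distribution, then Binomial(7, p); drinking habits are
    strongly bimodal, with many abstainers and many daily drinkers, so the
    count dispersion well exceeds the plain binomial).  For count7,
    baseline_mean/baseline_sd are the mean and sd of the weekly count and
    fix the Beta propensity spread.  ``planted_slope`` is the regression
    slope of age-residualized log ventricular volume on the factor, taken
    on the scale the association analysis uses (log scale for lognormal
    factors, the raw count for count7).
    """

    name: str
    kind: str
    baseline_mean: float
    baseline_sd: float
    planted_slope: float
    age_drift: float = 0.0
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "count7"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "lognormal" and self.baseline_sd <= 0:
            raise ValueError(f"{self.name}: baseline_sd must be > 0")
        if self.kind == "count7":
            if not (0.0 < self.baseline_mean < 7.0):
                raise ValueError(f"{self.name}: mean weekly count must lie in (0, 7)")
            if self.age_drift != 0.0:
                raise ValueError(f"{self.name}: age drift not supported for counts")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int
    ages: AgeDistribution = field(default_factory=AgeDistribution)
    sex_ratio_female: float = 0.44
    protocol_mix: dict[str, float] = field(default_factory=dict)
    repeat_scan_probability: float = 0.20
    longitudinal_sd: float = 0.0  # extra within-subject scatter on repeat scans
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not (0.0 <= self.sex_ratio_female <= 1.0):
            raise ValueError("sex_ratio_female must lie in [0, 1]")
        if not self.protocol_mix:
            raise ValueError("protocol_mix must not be empty")
        total = sum(self.protocol_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("protocol_mix weights must sum to 1")
        if not (0.0 <= self.repeat_scan_probability <= 1.0):
            raise ValueError("repeat_scan_probability must lie in [0, 1]")


# --------------------------------------------------------------------------- #
# presets

# structure -> (R^2 of quadratic age fit, % change 30->60, % of total at 30)
TABLE_STRUCTURES: dict[str, tuple[float, float, float]] = {
    "telencephalon": (0.297, -1.76, 39.6),
    "cortex": (0.320, -4.35, 20.9),
    "frontal_lobe": (0.298, -7.80, 6.98),
    "parietal_lobe": (0.090, -4.74, 3.72),
    "temporal_lobe": (0.115, -2.10, 5.30),
    "occipital_lobe": (0.005, -1.99, 2.68),
    "limbic_cortex": (0.002, -0.10, 1.74),
    "ventricles": (0.321, +59.8, 0.63),
    "anterior_ventricles": (0.308, +68.6, 0.44),
    "posterior_ventricles": (0.298, +54.7, 0.13),
    "inferior_ventricles": (0.203, +14.6, 0.07),
    "sylvian_fissure": (0.371, +20.3, 0.35),
    "periventricular_wmli": (0.410, +48.5, 0.03),
}

# sex differences as a share of the non-age variance: CSF spaces show a
# clear male-larger gap; tissue structures, expressed as fractions of total
# intracranial volume, differ little.  Shares keep every structure's sex
# offset compatible with its printed age-R^2 variance budget.
_CSF_SEX_VARIANCE_SHARE = 0.15
_TISSUE_SEX_VARIANCE_SHARE = 0.02

# curvature of the log trajectory: CSF expansion accelerates with age,
# tissue loss accelerates mildly
_CSF_CURVATURE = 5.0e-5
_TISSUE_CURVATURE = -5.0e-6


def _trajectory_variance(
    c1: float, c2: float, ages: AgeDistribution
) -> tuple[float, float, float]:
    """(total, between-decade, within-decade) variance of the mean trajectory
    over the age distribution; c0 is irrelevant for variances."""
    a, w = ages.grid()
    m = c1 * a + c2 * a * a
    mbar = float(np.sum(w * m))
    total = float(np.sum(w * (m - mbar) ** 2))
    decades = np.floor(a / 10.0) * 10.0
    between = 0.0
    for d in np.unique(decades):
        sel = decades == d
        wd = w[sel].sum()
        md = float(np.sum(w[sel] * m[sel]) / wd)
        between += wd * (md - mbar) ** 2
    return total, float(between), total - float(between)


def trajectory_from_summary(
    structure: str,
    r_squared: float,
    change_30_60_pct: float,
    size_at_30_pct: float,
    *,
    sex_variance_share: float,
    curvature: float,
    ages: AgeDistribution,
    sex_ratio_female: float = 0.5,
) -> TrajectorySpec:
    """Build a quadratic trajectory hitting the printed summary values.

    c0, c1 are solved from the size at 30 and the 30->60 change given the
    curvature.  The non-age variance is fixed by the stated R^2 under the
    age distribution,

        R^2 = Var(m(age)) / (Var(m(age)) + V_nonage),

    and split between the sex offset (``sex_variance_share`` of V_nonage,
    with r(1-r)*offset^2 the implied sex variance) and the between-subject
    residual sd, so a pooled quadratic age fit attains the stated R^2.
    """
    if not (0.0 <= sex_variance_share < 1.0):
        raise ValueError("sex_variance_share must lie in [0, 1)")
    dlog = math.log1p(change_30_60_pct / 100.0)
    c2 = curvature
    c1 = (dlog - 2700.0 * c2) / 30.0
    c0 = math.log(size_at_30_pct / 100.0) - 30.0 * c1 - 900.0 * c2
    var_m, _, _ = _trajectory_variance(c1, c2, ages)
    r = sex_ratio_female
    var_nonage = var_m * (1.0 - r_squared) / r_squared
    sex_offset = math.sqrt(sex_variance_share * var_nonage / (r * (1.0 - r)))
    var_resid = var_nonage * (1.0 - sex_variance_share)
    return TrajectorySpec(
        structure=structure,
        c0=c0,
        c1=c1,
        c2=c2,
        sex_offset=sex_offset,
        residual_sd=math.sqrt(var_resid),
        male_fraction_ref=1.0 - sex_ratio_female,
    )


def default_trajectories(
    ages: AgeDistribution | None = None, sex_ratio_female: float = 0.44
) -> dict[str, TrajectorySpec]:
    """Trajectory presets for the shipped structure set."""
    ages = ages or AgeDistribution()
    out = {}
    for name, (r2, change, size30) in TABLE_STRUCTURES.items():
        out[name] = trajectory_from_summary(
            name,
            r2,
            change,
            size30,
            sex_variance_share=(
                _CSF_SEX_VARIANCE_SHARE if change > 0 else _TISSUE_SEX_VARIANCE_SHARE
            ),
            curvature=_CSF_CURVATURE if change > 0 else _TISSUE_CURVATURE,
            ages=ages,
            sex_ratio_female=sex_ratio_female,
        )
    return out


def default_protocols() -> dict[str, ProtocolBiasSpec]:
    """Five site/protocol combinations mirroring the screening programme.

    Thick-slice protocols compress the dynamic range of small CSF spaces
    (bias slope < 1 anchored at log fraction -3.4, so the gap shrinks as
    ventricles grow) and cannot read below a partial-volume floor; the
    2.5 mm floor of -4.1 log units is the resolvability bound the thin-slice
    reference does not have.
    """
    anchor = -3.4

    def affine(slope: float) -> tuple[float, float]:
        return anchor * (1.0 - slope), slope

    b20, s20 = affine(0.93)
    b25, s25 = affine(0.85)
    return {
        "site1-1.2": ProtocolBiasSpec("site1-1.2", "site1", 1.2),
        "site1-2.0": ProtocolBiasSpec(
            "site1-2.0", "site1", 2.0, b20, s20, 0.03, -4.75
        ),
        "site2-1.2": ProtocolBiasSpec("site2-1.2", "site2", 1.2),
        "site2-2.0": ProtocolBiasSpec(
            "site2-2.0", "site2", 2.0, b20, s20, 0.03, -4.75
        ),
        "site3-2.5": ProtocolBiasSpec(
            "site3-2.5", "site3", 2.5, b25, s25, 0.05, -4.1
        ),
    }


# sample sizes per protocol in the screening programme
_PROTOCOL_COUNTS = {
    "site1-1.2": 2781,
    "site1-2.0": 1497,
    "site2-1.2": 2847,
    "site2-2.0": 3543,
    "site3-2.5": 11739,
}


def default_protocol_mix() -> dict[str, float]:
    total = sum(_PROTOCOL_COUNTS.values())
    return {k: v / total for k, v in _PROTOCOL_COUNTS.items()}


def identity_protocols() -> dict[str, ProtocolBiasSpec]:
    """A single distortion-free thin-slice protocol (observed = true)."""
    return {"ref-1.2": ProtocolBiasSpec("ref-1.2", "ref", 1.2)}


def default_risk_factors() -> dict[str, RiskFactorSpec]:
    """Risk-factor presets; planted slopes are the male-fifties values."""
    return {
        "glucose": RiskFactorSpec(
            "glucose", "lognormal", math.log(100.0), 0.13, 1.00e-3, 2.0e-3, "mg/dl"
        ),
        "abdominal_fat": RiskFactorSpec(
            "abdominal_fat", "lognormal", math.log(90.0), 0.45, 1.93e-2, 4.0e-3, "cm^2"
        ),
        "blood_pressure": RiskFactorSpec(
            "blood_pressure", "lognormal", math.log(128.0), 0.11, 2.20e-3, 3.0e-3,
            "mmHg",
        ),
        # bimodal drinking habits (abstainers and daily drinkers) make the
        # weekly-count sd far exceed the plain binomial value
        "alcohol_frequency": RiskFactorSpec(
            "alcohol_frequency", "count7", 2.0, 2.3, 1.24e-2, 0.0, "times/week"
        ),
    }


@dataclass(frozen=True)
class CohortPresets:
    trajectories: dict[str, TrajectorySpec]
    protocols: dict[str, ProtocolBiasSpec]
    risk_factors: dict[str, RiskFactorSpec]


def default_presets() -> CohortPresets:
    return CohortPresets(
        trajectories=default_trajectories(),
        protocols=default_protocols(),
        risk_factors=default_risk_factors(),
    )


def default_cohort_config(
    n_subjects: int = 5000,
    seed: int = 0,
    *,
    identity_bias: bool = False,
    repeat_scan_probability: float = 0.20,
) -> CohortConfig:
    mix = (
        {"ref-1.2": 1.0} if identity_bias else default_protocol_mix()
    )
    return CohortConfig(
        n_subjects=n_subjects,
        protocol_mix=mix,
        repeat_scan_probability=repeat_scan_probability,
        seed=seed,
    )


# resolution-level scan-count weights (1.2 / 2.0 / 2.5 mm)
_RESOLUTION_WEIGHTS = (0.2512, 0.2249, 0.5239)
# planted variance shares of the decade-binned three-way ANOVA
_ANOVA_SHARES = {"age": 0.302, "sex": 0.0412, "protocol": 0.0115}


def anova_preset(
    n_subjects: int = 10000, seed: int = 0
) -> tuple[TrajectorySpec, dict[str, ProtocolBiasSpec], CohortConfig]:
    """Ventricle-like cohort with planted decade-age/sex/protocol variance
    shares for the three-way ANOVA.

    The age-effect share is planted on the *between-decade* variance of the
    trajectory (what a decade-binned ANOVA attributes to age); within-decade
    trajectory variance counts toward the residual.  Protocol offsets are
    intercept-only so the planted share is exact.
    """
    ages = AgeDistribution()
    base = default_trajectories(ages)["ventricles"]
    _, between, within = _trajectory_variance(base.c1, base.c2, ages)
    total = between / _ANOVA_SHARES["age"]
    sex_ratio = 0.5
    sex_offset = math.sqrt(
        _ANOVA_SHARES["sex"] * total / (sex_ratio * (1 - sex_ratio))
    )
    pattern = np.array([0.0, 0.6, 1.0])
    weights = np.array(_RESOLUTION_WEIGHTS)
    centered = pattern - float(weights @ pattern)
    lam = math.sqrt(_ANOVA_SHARES["protocol"] * total / float(weights @ centered**2))
    offsets = lam * centered
    var_resid = total * (1.0 - sum(_ANOVA_SHARES.values())) - within
    if var_resid <= 0:  # pragma: no cover - preset arithmetic guard
        raise RuntimeError("planted ANOVA shares leave no residual variance")
    traj = TrajectorySpec(
        "ventricles", base.c0, base.c1, base.c2, sex_offset, math.sqrt(var_resid),
        male_fraction_ref=1.0 - sex_ratio,
    )
    protocols = {
        "pooled-1.2": ProtocolBiasSpec("pooled-1.2", "pooled", 1.2, offsets[0]),
        "pooled-2.0": ProtocolBiasSpec("pooled-2.0", "pooled", 2.0, offsets[1]),
        "pooled-2.5": ProtocolBiasSpec("pooled-2.5", "pooled", 2.5, offsets[2]),
    }
    config = CohortConfig(
        n_subjects=n_subjects,
        ages=ages,
        sex_ratio_female=sex_ratio,
        protocol_mix={k: float(w) for k, w in zip(protocols, weights)},
        repeat_scan_probability=0.0,
        seed=seed,
    )
    return traj, protocols, config


def risk_cohort_preset(
    n_subjects: int,
    seed: int = 0,
    *,
    sex: str = "M",
    decade: int = 50,
) -> tuple[dict[str, TrajectorySpec], dict[str, ProtocolBiasSpec], CohortConfig]:
    """Single-sex, single-decade cohort for risk-slope recovery.

    Protocol bias is intercept-only: gain distortion and censoring are
    removed upstream by calibration in the full pipeline, and the
    association regression absorbs intercept offsets with protocol dummies.
    """
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    ages = AgeDistribution(mean=54.5, sd=10.5, low=float(decade), high=decade + 10.0)
    traj = {"ventricles": default_trajectories()["ventricles"]}
    protocols = {
        "pooled-1.2": ProtocolBiasSpec("pooled-1.2", "pooled", 1.2, 0.0),
        "pooled-2.0": ProtocolBiasSpec("pooled-2.0", "pooled", 2.0, 0.06),
        "pooled-2.5": ProtocolBiasSpec("pooled-2.5", "pooled", 2.5, 0.15),
    }
    config = CohortConfig(
        n_subjects=n_subjects,
        ages=ages,
        sex_ratio_female=1.0 if sex == "F" else 0.0,
        protocol_mix={k: w for k, w in zip(protocols, _RESOLUTION_WEIGHTS)},
        repeat_scan_probability=0.20,
        seed=seed,
    )
    return traj, protocols, config


# --------------------------------------------------------------------------- #
# generators


def _sex_term(spec: TrajectorySpec, is_male: np.ndarray) -> np.ndarray:
    """Male-minus-female gap centred so the pooled curve stays the mean
    trajectory at the reference sex mix."""
    return spec.sex_offset * (
        np.asarray(is_male, float) - spec.male_fraction_ref
    )


def generate_cohort(
    config: CohortConfig,
    trajectories: dict[str, TrajectorySpec],
    biases: dict[str, ProtocolBiasSpec],
) -> pd.DataFrame:
    """Generate one row per scan.

    Latent model: each subject carries one age-invariant residual per
    structure; the true log volume fraction at a scan is the trajectory mean
    at scan age plus sex offset plus that residual.  Observation applies the
    scan protocol's affine bias, extra noise and censoring floor.  Emitted
    simulation-only columns: ``latent_<structure>`` (true log fraction) and
    ``latent_resid_<structure>`` (residual after removing age and sex
    terms), used by oracles and by the clinical generator.
    """
    unknown = set(config.protocol_mix) - set(biases)
    if unknown:
        raise ValueError(f"protocol_mix references unknown protocols: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    age1 = config.ages.rvs(n, rng)
    is_male = rng.random(n) >= config.sex_ratio_female
    proto_ids = list(config.protocol_mix)
    weights = np.array([config.protocol_mix[p] for p in proto_ids])
    proto_idx = rng.choice(len(proto_ids), size=n, p=weights)
    has_repeat = rng.random(n) < config.repeat_scan_probability
    dt = rng.uniform(1.0, 2.0, size=n)

    total_vol = np.exp(rng.normal(LOG_TOTAL_VOLUME_MEAN, LOG_TOTAL_VOLUME_SD, n))
    comp_fracs = rng.gamma(COMPARTMENT_CONCENTRATION * COMPARTMENT_BASE, size=(n, 3))
    comp_fracs /= comp_fracs.sum(axis=1, keepdims=True)

    resid = {
        s: rng.normal(0.0, spec.residual_sd, n) for s, spec in trajectories.items()
    }
    long_noise = {
        s: (
            rng.normal(0.0, config.longitudinal_sd, n)
            if config.longitudinal_sd > 0
            else np.zeros(n)
        )
        for s in trajectories
    }

    # scan-level arrays: first scans for everyone, second scans for a subset
    rep = np.flatnonzero(has_repeat)
    subj_idx = np.concatenate([np.arange(n), rep])
    ordinal = np.concatenate([np.ones(n, int), np.full(rep.size, 2)])
    age = np.concatenate([age1, age1[rep] + dt[rep]])

    obs_cols: dict[str, np.ndarray] = {}
    lat_cols: dict[str, np.ndarray] = {}
    res_cols: dict[str, np.ndarray] = {}
    pidx_scan = proto_idx[subj_idx]
    for s, spec in trajectories.items():
        extra = np.where(ordinal > 1, long_noise[s][subj_idx], 0.0)
        true_log = (
            spec.mean_log_frac(age)
            + _sex_term(spec, is_male[subj_idx])
            + resid[s][subj_idx]
            + extra
        )
        obs_log = np.empty_like(true_log)
        for k, pid in enumerate(proto_ids):
            sel = pidx_scan == k
            obs_log[sel] = biases[pid].observe(true_log[sel], rng)
        lat_cols[s] = true_log
        res_cols[s] = resid[s][subj_idx] + extra
        obs_cols[s] = obs_log

    total_scan = total_vol[subj_idx]
    comp_scan = comp_fracs[subj_idx] * total_scan[:, None]
    subject_ids = np.array([f"S{i:06d}" for i in range(n)])

    df = pd.DataFrame(
        {
            "subject_id": subject_ids[subj_idx],
            "scan_id": [
                f"{subject_ids[i]}-{o}" for i, o in zip(subj_idx, ordinal)
            ],
            "scan_ordinal": ordinal,
            "age": age,
            "sex": np.where(is_male[subj_idx], "M", "F"),
            "site": [biases[proto_ids[k]].site for k in pidx_scan],
            "protocol_id": [proto_ids[k] for k in pidx_scan],
            "slice_resolution_mm": [
                biases[proto_ids[k]].slice_resolution_mm for k in pidx_scan
            ],
            "vol_brain": comp_scan[:, 0],
            "vol_sulci": comp_scan[:, 1],
            "vol_cranial_space": comp_scan[:, 2],
            "total_volume_mm3": comp_scan.sum(axis=1),
        }
    )
    for s in trajectories:
        df[f"vol_{s}"] = np.exp(obs_cols[s]) * total_scan
    for s in trajectories:
        df[f"latent_{s}"] = lat_cols[s]
        df[f"latent_resid_{s}"] = res_cols[s]
    df = df.sort_values(["subject_id", "scan_ordinal"], kind="mergesort")
    return df.reset_index(drop=True)


def _count7_marginal(mean_count: float, sd_count: float):
    """Frozen marginal for the weekly count: beta-binomial matching the
    requested mean and sd, or plain binomial when the sd is at or below
    the binomial value.

    Var(x) = 7*mu*(1-mu) + 42*var_p with mu = mean_count/7 and var_p the
    Beta propensity variance.
    """
    mu = mean_count / 7.0
    var_p = (sd_count**2 - 7.0 * mu * (1.0 - mu)) / 42.0
    if var_p <= 0:
        return stats.binom(7, mu)
    cap = mu * (1.0 - mu)
    if var_p >= cap:
        raise ValueError("count7 baseline_sd exceeds the maximal beta-binomial spread")
    nu = cap / var_p - 1.0
    return stats.betabinom(7, mu * nu, (1.0 - mu) * nu)


def _count7_draw(
    spec: RiskFactorSpec, r: np.ndarray, var_r: float, rng: np.random.Generator
) -> np.ndarray:
    """Weekly counts with an exact planted regression slope.

    The count is the marginal quantile transform x = F^{-1}(Phi(z)) of a
    latent normal z = rho*(r/sd_r) + sqrt(1-rho^2)*eps (Gaussian copula).
    With s = r/sd_r standard normal and E[s|z] = rho*z,

        Cov(r, x) = sd_r * rho * E[z * F^{-1}(Phi(z))],

    so rho is solved from slope = Cov(r, x)/Var(x); the quantile factor
    E[z*g(z)] is evaluated by quadrature.  This keeps the marginal exactly
    beta-binomial (bounded, bimodal) while the regression of the volume
    residual on the count recovers the planted slope in expectation.
    """
    marginal = _count7_marginal(spec.baseline_mean, spec.baseline_sd)
    if spec.planted_slope == 0.0:
        return marginal.rvs(size=r.size, random_state=rng)
    cdf = marginal.cdf(np.arange(8))

    def quantile(u: np.ndarray) -> np.ndarray:
        return np.searchsorted(cdf, u, side="left").clip(0, 7)

    zg = np.linspace(-8.0, 8.0, 20001)
    w = stats.norm.pdf(zg)
    w /= w.sum()
    c_factor = float(np.sum(w * zg * quantile(stats.norm.cdf(zg))))
    sd_r = math.sqrt(var_r)
    rho = spec.planted_slope * float(marginal.var()) / (sd_r * c_factor)
    if not (-1.0 < rho < 1.0):
        raise ValueError("planted count7 slope not attainable at this dispersion")
    z = rho * (r / sd_r) + math.sqrt(1.0 - rho * rho) * rng.standard_normal(r.size)
    return quantile(stats.norm.cdf(z))


from brainnorm.risk import FACTOR_COLUMNS as _FACTOR_COLUMNS  # noqa: E402


def generate_clinical(
    cohort: pd.DataFrame,
    specs: dict[str, RiskFactorSpec],
    seed: int,
    structure: str = "ventricles",
) -> pd.DataFrame:
    """One clinical row per subject, coupled to the latent volume residual.

    Lognormal factors are drawn conditionally Gaussian on the log scale with
    coupling gamma = slope * var_t / var_r, which makes the regression of
    the age-residualized log volume on the log factor recover the planted
    slope in expectation while preserving the factor's marginal variance.
    Weekly counts use a Gaussian-copula quantile construction with an exact
    beta-binomial marginal (see _count7_draw).
    """
    unknown = set(specs) - set(_FACTOR_COLUMNS)
    if unknown:
        raise ValueError(f"unknown risk factors: {sorted(unknown)}")
    resid_col = f"latent_resid_{structure}"
    if resid_col not in cohort.columns:
        raise ValueError(f"cohort lacks latent residual column {resid_col!r}")

    first = cohort[cohort["scan_ordinal"] == 1]
    rng = np.random.default_rng(seed)
    r = first[resid_col].to_numpy()
    age = first["age"].to_numpy()
    var_r = float(np.var(r))

    out = pd.DataFrame(
        {
            "subject_id": first["subject_id"].to_numpy(),
            "age": age,
            "sex": first["sex"].to_numpy(),
        }
    )
    for name in _FACTOR_COLUMNS:
        if name not in specs:
            continue
        spec = specs[name]
        if spec.kind == "lognormal":
            var_t = spec.baseline_sd**2
            gamma = spec.planted_slope * var_t / var_r
            noise_var = var_t - gamma**2 * var_r
            if noise_var <= 0:
                raise ValueError(f"{name}: planted slope exceeds factor variance")
            t = (
                spec.baseline_mean
                + spec.age_drift * (age - 50.0)
                + gamma * r
                + rng.normal(0.0, math.sqrt(noise_var), r.size)
            )
            out[_FACTOR_COLUMNS[name]] = np.exp(t)
        else:
            out[_FACTOR_COLUMNS[name]] = _count7_draw(spec, r, var_r, rng)
    return out.reset_index(drop=True)


def config_to_json_dict(
    config: CohortConfig,
    trajectories: dict[str, TrajectorySpec],
    biases: dict[str, ProtocolBiasSpec],
    risk_factors: dict[str, RiskFactorSpec] | None = None,
) -> dict:
    """Full generator configuration as a JSON-serializable dict."""
    d = {
        "config": asdict(config),
        "trajectories": {k: asdict(v) for k, v in trajectories.items()},
        "protocols": {
            k: {
                key: (None if key == "floor_log" and not np.isfinite(val) else val)
                for key, val in asdict(v).items()
            }
            for k, v in biases.items()
        },
    }
    if risk_factors is not None:
        d["risk_factors"] = {k: asdict(v) for k, v in risk_factors.items()}
    return d
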