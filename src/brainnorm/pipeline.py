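"""End-to-end orchestration: normalize -> fit -> calibrate -> verify ->
normative -> risk, with JSON-line logging and config-stamped artifacts.

Each stage reads only upstream artifacts and never mutates its inputs;
rerunning with the same config and seed reproduces every table bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from brainnorm import harmonize, normative, risk, volumetry
from brainnorm.trajectories import fit_age_polynomial, fit_curves, windowed_age_stats

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    volumes_path: str
    out_dir: str
    clinical_path: str | None = None
    structure: str = "ventricles"
    reference_protocol: str = ""  # default: a protocol with the finest slices
    age_range: tuple[int, int] = (30, 75)
    window_half_width: int = 2
    polynomial_order: int = 2
    min_window_count: int = 20
    quantile_levels: tuple[float, ...] = normative.DEFAULT_QUANTILE_LEVELS
    alpha: float = 0.05
    bonferroni_divisor: int = 4
    z_threshold: float = 2.0
    make_figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polynomial_order not in (2, 3):
            raise ValueError("polynomial_order must be 2 or 3")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def write(self, stage: str, **payload) -> None:
        rec = {"t": round(time.time(), 3), "stage": stage, **payload}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def _stage(log: _Log, name: str):
    class _Ctx:
        def __enter__(self):
            log.write(name, event="start")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.write(name, event="error", error=str(exc))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.write(name, event="done")

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    (out / "config.json").write_text(
        json.dumps({"config": asdict(config), "config_hash": config.hash()}, indent=2)
    )

    with _stage(log, "load"):
        volumes = volumetry.read_volume_table(config.volumes_path)
        first = volumetry.select_first_scan(volumes)
        log.write("load", n_scans=len(volumes), n_subjects=len(first))

    with _stage(log, "trajectories"):
        structures = [
            c.removeprefix("vol_")
            for c in volumetry.structure_columns(volumes)
            if c.removeprefix("vol_") not in ("brain", "sulci", "cranial_space")
        ]
        fits = []
        for s in structures:
            logv = volumetry.log_transform(volumetry.proportional_normalize(first, s))
            fs = fit_age_polynomial(
                logv, first["age"], order=config.polynomial_order, structure=s
            )
            fits.append(fs.to_dict())
            log.write("trajectories", structure=s, coefficients=fs.coefficients)
        pd.DataFrame(fits).to_csv(out / "trajectory_fits.csv", index=False)

    structure = config.structure
    logvol = volumetry.log_transform(
        volumetry.proportional_normalize(volumes, structure)
    )
    vols = volumes.assign(_logvol=np.asarray(logvol, float))

    with _stage(log, "pooling_gate"):
        gates = []
        for res, sub in vols.groupby("slice_resolution_mm"):
            if sub["site"].nunique() < 2:
                continue
            pooled, p = harmonize.site_pooling_gate(sub, "_logvol")
            gates.append(
                {"slice_resolution_mm": float(res), "pooled": pooled, "p_value": p}
            )
        (out / "pooling_gate.json").write_text(json.dumps(gates, indent=2))

    with _stage(log, "anova"):
        pre = harmonize.anova_effect_sizes(vols, "_logvol")
        pre.to_csv(out / "anova_pre_calibration.csv")

    with _stage(log, "calibrate"):
        ref = config.reference_protocol
        if not ref:
            finest = vols.loc[vols["slice_resolution_mm"].idxmin()]
            ref = str(finest["protocol_id"])
        models = harmonize.build_calibration_models(
            vols,
            vols["_logvol"],
            reference_protocol=ref,
            structure=structure,
            min_count=config.min_window_count,
        )
        for sex, model in models.items():
            model.to_json(out / f"calibration_{sex}.json")
        vols["_logvol_cal"] = harmonize.apply_calibration(
            vols, vols["_logvol"], models
        )
        post, p_protocol = harmonize.verify_calibration(
            vols, models, vols["_logvol"]
        )
        post.to_csv(out / "anova_post_calibration.csv")
        log.write("calibrate", reference_protocol=ref, p_protocol_post=p_protocol)

    with _stage(log, "normative"):
        first_cal = volumetry.select_first_scan(vols)
        charts = {}
        for sex, sub in first_cal.groupby("sex"):
            stats_ = windowed_age_stats(
                sub["_logvol_cal"],
                sub["age"],
                half_width=config.window_half_width,
                age_range=config.age_range,
            )
            curve = fit_curves(
                stats_,
                structure=structure,
                sex=str(sex),
                protocol_id=ref,
                min_count=config.min_window_count,
            )
            chart = normative.boosted_quantile_chart(
                sub["_logvol_cal"],
                sub["age"],
                config.quantile_levels,
                curve=curve,
                structure=structure,
                sex=str(sex),
                random_state=config.seed,
            )
            chart.to_json(out / f"quantile_chart_{sex}.json")
            charts[str(sex)] = (curve, chart, sub)
            model = normative.NormativeModel(curve, config.z_threshold)
            flagged = normative.flag_large_ventricles(sub, sub["_logvol_cal"], model)
            flagged.to_csv(out / f"flagged_{sex}.csv", index=False)
            hist = normative.decade_histograms(sub, sub["_logvol_cal"])
            (out / f"decade_histograms_{sex}.json").write_text(
                json.dumps(hist, indent=2)
            )
            log.write("normative", sex=str(sex), n_flagged=len(flagged))
        if config.make_figures:
            _render_figures(out, charts)

    if config.clinical_path is None or not Path(config.clinical_path).exists():
        log.write("risk", event="skipped", reason="no clinical table")
        warnings.warn("clinical table missing; risk stage skipped")
    else:
        with _stage(log, "risk"):
            clinical = pd.read_csv(
                config.clinical_path, dtype={"subject_id": str}
            )
            grid = risk.run_table3(
                volumes,
                clinical,
                structure=structure,
                min_window_count=config.min_window_count,
            )
            grid.to_csv(out / "risk_grid.csv", index=False)

    log.write("pipeline", event="complete", config_hash=config.hash())
    return out


def _render_figures(out: Path, charts: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, max(len(charts), 1), figsize=(6 * len(charts), 4))
    axes = np.atleast_1d(axes)
    for ax, (sex, (curve, chart, sub)) in zip(axes, charts.items()):
        ax.scatter(sub["age"], sub["_logvol_cal"], s=2, alpha=0.15, color="gray")
        ages = np.asarray(chart.ages)
        for lv in chart.levels:
            ax.plot(ages, chart.normal_curves[lv], "-", lw=1)
            ax.plot(ages, chart.boosted_curves[lv], ":", lw=1)
        ax.set_title(f"{curve.structure} ({sex})")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("log relative volume")
    fig.tight_layout()
    fig.savefig(out / "centile_chart.png", dpi=120)
    plt.close(fig)
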