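"""Protocol effects and cross-resolution calibration of ventricular volume.

On the planted-variance cohort: (1) checks that same-resolution sites may
be pooled; (2) decomposes log ventricular volume variance into protocol,
sex and decade-of-age contributions with a three-way ANOVA (eta-squared);
(3) calibrates thick-slice protocols to the 1.2 mm reference by
age-conditional moment matching and verifies the protocol effect collapses.
"""

from pathlib import Path

import numpy as np

from brainnorm import experiments, harmonize, synthetic, volumetry

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2024
N_SUBJECTS = 10000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # pooling gate on the realistic five-protocol cohort (two sites at each
    # of 1.2 and 2.0 mm, no planted site effect)
    presets = synthetic.default_presets()
    cfg = synthetic.default_cohort_config(6000, seed=SEED)
    cohort = synthetic.generate_cohort(cfg, presets.trajectories, presets.protocols)
    logv = volumetry.log_transform(
        volumetry.proportional_normalize(cohort, "ventricles")
    )
    df = cohort.assign(_logvol=np.asarray(logv, float))
    for res, sub in df.groupby("slice_resolution_mm"):
        if sub["site"].nunique() < 2:
            continue
        pooled, p = harmonize.site_pooling_gate(sub, "_logvol")
        print(f"sites at {res} mm: p = {p:.3f} -> {'pool' if pooled else 'keep apart'}")

    # variance decomposition and calibration on the planted-share cohort
    pre, post, p_post = experiments.anova_recovery(SEED, N_SUBJECTS)
    pre.to_csv(OUT / "anova_pre_calibration.csv")
    post.to_csv(OUT / "anova_post_calibration.csv")
    print("\npre-calibration eta-squared (% of total variance):")
    print(
        pre.loc[["decade", "sex", "protocol_id"], "eta_squared_percent"]
        .round(2)
        .to_string()
    )
    print(
        f"\npost-calibration protocol share: "
        f"{post.loc['protocol_id', 'eta_squared_percent']:.4f}% "
        f"(p = {p_post:.3f}) -> protocol effect removed"
    )
    print(f"wrote ANOVA tables to {OUT}")


if __name__ == "__main__":
    main()
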