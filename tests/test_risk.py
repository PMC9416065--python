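"""Risk-factor regression: design preparation, robust fits and the grid."""

import numpy as np
import pandas as pd
import pytest

from brainnorm import risk, synthetic, volumetry
from brainnorm.trajectories import AgeVolumeCurve


@pytest.fixture(scope="module")
def risk_cohort():
    traj, protos, cfg = synthetic.risk_cohort_preset(3000, seed=51)
    cohort = synthetic.generate_cohort(cfg, traj, protos)
    clinical = synthetic.generate_clinical(
        cohort, synthetic.default_risk_factors(), seed=52
    )
    logv = volumetry.log_transform(
        volumetry.proportional_normalize(cohort, "ventricles")
    )
    return cohort, clinical, logv


@pytest.fixture(scope="module")
def designs(risk_cohort):
    cohort, clinical, logv = risk_cohort
    curves = risk._reference_curves(cohort, logv)
    return risk.prepare_regression_inputs(
        cohort, logv, clinical, curves, decades=(50,)
    )


class TestPrepareInputs:
    def test_subject_on_mean_curve_has_zero_volume_covariate(self):
        curve = AgeVolumeCurve(
            "ventricles", "M", "ref", (30, 75), (-4.8, 0.0, 0.0), (0.25, 0.0, 0.0)
        )
        volumes = pd.DataFrame(
            {
                "subject_id": ["a"],
                "scan_id": ["a-1"],
                "scan_ordinal": [1],
                "age": [55.0],
                "sex": ["M"],
                "protocol_id": ["p"],
            }
        )
        clinical = pd.DataFrame(
            {
                "subject_id": ["a"],
                "glucose_mg_dl": [100.0],
                "abdominal_fat_cm2": [90.0],
                "blood_pressure_max_mmhg": [130.0],
                "alcohol_per_week": [2],
            }
        )
        designs = risk.prepare_regression_inputs(
            volumes, pd.Series([-4.8]), clinical, {"M": curve}, decades=(50,)
        )
        assert designs[("M", 50)]["vol_resid"].iloc[0] == pytest.approx(0.0)

    def test_age_independent_factor_shifts_by_constant_only(self, risk_cohort):
        cohort, clinical, logv = risk_cohort
        clin2 = clinical.copy()
        clin2["glucose_mg_dl"] = 100.0  # constant factor
        curves = risk._reference_curves(cohort, logv)
        d = risk.prepare_regression_inputs(
            cohort, logv, clin2, curves, decades=(50,)
        )[("M", 50)]
        assert np.allclose(d["glucose"], d["glucose"].iloc[0])

    def test_decade_bins_match_brute_force_counts(self, risk_cohort):
        cohort, clinical, logv = risk_cohort
        curves = risk._reference_curves(cohort, logv)
        designs = risk.prepare_regression_inputs(
            cohort, logv, clinical, curves, decades=(40, 50, 60)
        )
        merged = cohort.merge(clinical[["subject_id"]], on="subject_id")
        for (sex, dec), d in designs.items():
            ages = merged.loc[merged["sex"] == sex, "age"]
            expected = ((ages >= dec) & (ages < dec + 10)).sum()
            assert len(d) == expected

    def test_missing_clinical_column_rejected(self, risk_cohort):
        cohort, clinical, logv = risk_cohort
        curves = risk._reference_curves(cohort, logv)
        with pytest.raises(ValueError, match="glucose_mg_dl"):
            risk.prepare_regression_inputs(
                cohort,
                logv,
                clinical.drop(columns=["glucose_mg_dl"]),
                curves,
            )


class TestRobustFit:
    def test_null_factor_slope_within_noise(self, risk_cohort):
        cohort, clinical, logv = risk_cohort
        rng = np.random.default_rng(0)
        clin2 = clinical.copy()
        clin2["glucose_mg_dl"] = np.exp(rng.normal(np.log(100), 0.13, len(clinical)))
        curves = risk._reference_curves(cohort, logv)
        d = risk.prepare_regression_inputs(
            cohort, logv, clin2, curves, decades=(50,)
        )[("M", 50)]
        res = risk.robust_fit(d, "glucose")
        assert abs(res.slope) < 3 * res.slope_se
        assert not res.significant_at_bonferroni

    def test_planted_alcohol_slope_recovered(self, designs):
        res = risk.robust_fit(designs[("M", 50)], "alcohol_frequency")
        assert res.slope == pytest.approx(1.24e-2, abs=3 * res.slope_se)
        assert res.p_value < 0.05

    def test_huber_resists_contamination_better_than_ols(self, designs):
        # OLS-vs-Huber oracle: adding +5-sd outliers to 5% of responses moves
        # the Huber slope by less than the OLS slope moves
        import statsmodels.api as sm

        d = designs[("M", 50)].copy()
        X = risk._design_matrix(d, "alcohol_frequency")
        y = d["vol_resid"].to_numpy().copy()
        base_ols = sm.OLS(y, X).fit().params["alcohol_frequency"]
        base_huber = (
            sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit().params["alcohol_frequency"]
        )
        rng = np.random.default_rng(1)
        idx = rng.choice(len(y), int(0.05 * len(y)), replace=False)
        sd = y.std()
        # contamination correlated with the factor to actually shift slopes
        x = d["alcohol_frequency"].to_numpy()
        idx = idx[x[idx] > np.median(x)]
        y[idx] += 5 * sd
        ols_shift = abs(
            sm.OLS(y, X).fit().params["alcohol_frequency"] - base_ols
        )
        huber_shift = abs(
            sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit().params["alcohol_frequency"]
            - base_huber
        )
        assert huber_shift < 0.5 * ols_shift

    def test_slope_equivariant_under_factor_scaling(self, designs):
        d = designs[("M", 50)].copy()
        res1 = risk.robust_fit(d, "glucose")
        d["glucose"] = d["glucose"] * 4.0
        res2 = risk.robust_fit(d, "glucose")
        assert res2.slope == pytest.approx(res1.slope / 4.0, rel=1e-6)

    def test_small_cell_rejected(self, designs):
        with pytest.raises(ValueError, match="too small"):
            risk.robust_fit(designs[("M", 50)].head(10), "glucose")

    def test_bonferroni_flag_is_quarter_alpha(self):
        # flags must equal the direct comparison p < 0.05/4
        r = risk.RiskRegressionResult(
            "glucose", "M", 50, 100, 1e-3, 1e-4, 0.02, 0.01, 0.01, True, False
        )
        assert r.significant_at_005 and not r.significant_at_bonferroni
        with pytest.raises(ValueError):
            risk.RiskRegressionResult(
                "glucose", "M", 50, 100, 1e-3, 1e-4, 0.2, 0.01, 0.01, False, True
            )


class TestTypeIError:
    def test_null_slope_test_calibrated_at_five_percent(self):
        # 500 replicates at reduced n: the slope test under a planted null
        # rejects ~5% of the time at alpha = 0.05
        rng = np.random.default_rng(7)
        n = 150
        reps = 500
        rejections = 0
        for _ in range(reps):
            d = pd.DataFrame(
                {
                    "vol_resid": rng.normal(0, 0.24, n),
                    "glucose": rng.normal(4.6, 0.13, n),
                    "protocol_id": rng.choice(["a", "b"], n),
                    "repeat_scan": rng.integers(0, 2, n),
                }
            )
            res = risk.robust_fit(d, "glucose")
            rejections += res.p_value < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate == pytest.approx(0.05, abs=3.5 * se)


class TestRunTable3:
    @pytest.fixture(scope="class")
    def grid(self):
        presets = synthetic.default_presets()
        config = synthetic.default_cohort_config(
            6000, seed=61, identity_bias=True
        )
        cohort = synthetic.generate_cohort(
            config,
            {"ventricles": presets.trajectories["ventricles"]},
            synthetic.identity_protocols(),
        )
        clinical = synthetic.generate_clinical(
            cohort, presets.risk_factors, seed=62
        )
        return risk.run_table3(cohort, clinical)

    def test_grid_covers_all_cells(self, grid):
        # 4 factors x 2 sexes x 3 decades x 2 normalization variants
        assert len(grid) == 48
        assert set(grid["normalization"]) == {"proportional", "residuals"}

    def test_planted_signs_recovered_in_well_powered_cells(self, grid):
        # all planted slopes are positive; cells flagged significant must
        # recover a positive slope
        ok = grid[(grid["error"] == "") & grid["significant_at_005"]]
        assert len(ok) > 0
        assert (ok["slope"] > 0).all()

    def test_normalization_variants_agree_for_strong_effects(self, grid):
        strong = grid[(grid["factor"] == "alcohol_frequency") & (grid["error"] == "")]
        piv = strong.pivot_table(
            index=["sex", "decade"],
            columns="normalization",
            values="significant_at_005",
        )
        agree = (piv["proportional"] == piv["residuals"]).mean()
        assert agree >= 0.8


class TestBinnedEffectPlot:
    def test_single_bin_reproduces_grand_mean_and_se(self, designs):
        d = designs[("M", 50)]
        x = d["alcohol_frequency"]
        out = risk.binned_effect_plot(d, "alcohol_frequency", [x.min(), x.max() + 1])
        assert len(out) == 1
        vals = d["vol_resid"]
        assert out["mean"].iloc[0] == pytest.approx(vals.mean())
        assert out["se"].iloc[0] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(len(vals))
        )

    def test_bin_counts_conserve_rows(self, designs):
        d = designs[("M", 50)]
        x = d["alcohol_frequency"]
        edges = [x.min(), 2, 4, x.max() + 1e-9]
        out = risk.binned_effect_plot(d, "alcohol_frequency", edges)
        assert out["n"].sum() == len(d)

    def test_planted_positive_slope_gives_increasing_bin_means(self, designs):
        d = designs[("M", 50)]
        out = risk.binned_effect_plot(d, "alcohol_frequency", [0, 2, 4, 8])
        means = out["mean"].to_numpy()
        assert means[-1] > means[0]
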