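"""Generator: presets, determinism, latent structure and planted couplings."""

import math

import numpy as np
import pandas as pd
import pytest

from brainnorm import synthetic, volumetry


class TestPresets:
    def test_ventricle_mean_curve_at_30(self, presets):
        v = presets.trajectories["ventricles"]
        assert float(v.mean_log_frac(30.0)) == pytest.approx(math.log(0.0063), abs=1e-9)

    @pytest.mark.parametrize(
        "structure,change",
        [("ventricles", 59.8), ("cortex", -4.35), ("frontal_lobe", -7.80)],
    )
    def test_change_30_60_matches_published_summary(self, presets, structure, change):
        t = presets.trajectories[structure]
        assert t.change_30_60_percent() == pytest.approx(change, abs=1e-6)

    def test_all_structures_have_valid_log_range(self, presets):
        ages = np.linspace(20, 90, 71)
        for t in presets.trajectories.values():
            m = t.mean_log_frac(ages)
            assert np.all((m > -12) & (m < 0))

    def test_floor_only_on_thick_slices(self, presets):
        for p in presets.protocols.values():
            if p.slice_resolution_mm <= 1.2:
                assert not np.isfinite(p.floor_log)

    def test_risk_presets_carry_published_slopes(self, presets):
        assert presets.risk_factors["alcohol_frequency"].planted_slope == 1.24e-2
        assert presets.risk_factors["blood_pressure"].planted_slope == 2.20e-3


class TestGenerateCohort:
    def test_identical_seed_gives_byte_identical_tables(self, presets):
        config = synthetic.default_cohort_config(300, seed=42)
        a = synthetic.generate_cohort(config, presets.trajectories, presets.protocols)
        b = synthetic.generate_cohort(config, presets.trajectories, presets.protocols)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_identity_bias_observed_equals_latent(self, identity_cohort):
        logfrac = volumetry.log_transform(
            volumetry.proportional_normalize(identity_cohort, "ventricles")
        )
        assert np.allclose(logfrac, identity_cohort["latent_ventricles"], atol=1e-10)

    def test_unknown_protocol_in_mix_rejected(self, presets):
        config = synthetic.default_cohort_config(50, seed=0)
        with pytest.raises(ValueError, match="unknown protocols"):
            synthetic.generate_cohort(
                config, presets.trajectories, synthetic.identity_protocols()
            )

    def test_young_mean_fraction_matches_monte_carlo_oracle(self, presets):
        config = synthetic.default_cohort_config(5000, seed=3, identity_bias=True)
        traj = {"ventricles": presets.trajectories["ventricles"]}
        cohort = synthetic.generate_cohort(
            config, traj, synthetic.identity_protocols()
        )
        sel = cohort["age"].between(29, 31) & (cohort["scan_ordinal"] == 1)
        frac = volumetry.proportional_normalize(cohort[sel], "ventricles")
        # oracle: direct Monte-Carlo average of the generative mean curve over
        # the same age band and sex mix, with the lognormal mean correction
        rng = np.random.default_rng(99)
        t = traj["ventricles"]
        ages = rng.uniform(29, 31, 200_000)
        male = rng.random(200_000) >= config.sex_ratio_female
        sex_term = t.sex_offset * (male.astype(float) - t.male_fraction_ref)
        draws = np.exp(
            t.mean_log_frac(ages)
            + sex_term
            + rng.normal(0, t.residual_sd, 200_000)
        )
        mc_mean = draws.mean()
        se = frac.std() / np.sqrt(sel.sum())
        assert frac.mean() == pytest.approx(mc_mean, abs=3.5 * se)

    def test_repeat_scans_share_subject_latent(self, presets):
        config = synthetic.default_cohort_config(
            800, seed=7, identity_bias=True, repeat_scan_probability=0.5
        )
        cohort = synthetic.generate_cohort(
            config,
            {"ventricles": presets.trajectories["ventricles"]},
            synthetic.identity_protocols(),
        )
        by_subj = cohort.groupby("subject_id")
        both = by_subj.filter(lambda g: len(g) == 2)
        assert len(both) > 0
        for _, g in both.groupby("subject_id"):
            r = g["latent_resid_ventricles"].to_numpy()
            assert r[0] == pytest.approx(r[1], abs=1e-12)
            ages = g.sort_values("scan_ordinal")["age"].to_numpy()
            assert 1.0 <= ages[1] - ages[0] <= 2.0

    def test_total_volume_exceeds_structure_volumes(self, biased_cohort):
        total = biased_cohort["total_volume_mm3"]
        for col in volumetry.structure_columns(biased_cohort):
            assert (biased_cohort[col] <= total).all()


class TestCensoring:
    def test_floor_only_raises_observed_volumes(self, presets):
        config = synthetic.CohortConfig(
            n_subjects=2000,
            protocol_mix={"site3-2.5": 1.0},
            repeat_scan_probability=0.0,
            seed=21,
        )
        traj = {"ventricles": presets.trajectories["ventricles"]}
        cohort = synthetic.generate_cohort(config, traj, presets.protocols)
        spec = presets.protocols["site3-2.5"]
        obs = np.log(
            volumetry.proportional_normalize(cohort, "ventricles").to_numpy()
        )
        assert np.all(obs >= spec.floor_log - 1e-12)
        # without the floor the affine map would put some observations below
        uncensored = (
            spec.bias_intercept + spec.bias_slope * cohort["latent_ventricles"]
        )
        assert (uncensored < spec.floor_log).any()
        assert np.all(obs >= uncensored - spec.extra_noise_sd * 6)

    def test_censored_fraction_decreases_with_age_for_growing_structure(
        self, presets
    ):
        config = synthetic.CohortConfig(
            n_subjects=6000,
            protocol_mix={"site3-2.5": 1.0},
            repeat_scan_probability=0.0,
            seed=22,
        )
        traj = {"ventricles": presets.trajectories["ventricles"]}
        cohort = synthetic.generate_cohort(config, traj, presets.protocols)
        spec = presets.protocols["site3-2.5"]
        obs = np.log(volumetry.proportional_normalize(cohort, "ventricles"))
        at_floor = np.isclose(obs, spec.floor_log)
        young = cohort["age"] < 45
        old = cohort["age"] > 60
        assert at_floor[young].mean() > at_floor[old].mean()


class TestPooledCurveConvergence:
    def test_empirical_age_curve_matches_generative_polynomial(self, presets):
        # identity observation; window means must converge to the trajectory
        config = synthetic.default_cohort_config(
            20000, seed=13, identity_bias=True, repeat_scan_probability=0.0
        )
        t = presets.trajectories["ventricles"]
        cohort = synthetic.generate_cohort(
            config, {"ventricles": t}, synthetic.identity_protocols()
        )
        logv = np.log(volumetry.proportional_normalize(cohort, "ventricles"))
        ages = cohort["age"].to_numpy()
        for lo in (35, 45, 55, 65):
            sel = (ages >= lo) & (ages < lo + 2)
            n = sel.sum()
            # closed-form oracle: quadrature of the mean curve over the band
            grid = np.linspace(lo, lo + 2, 200)
            a, w = config.ages.grid()
            wsel = (a >= lo) & (a < lo + 2)
            oracle = float(np.sum(w[wsel] * t.mean_log_frac(a[wsel])) / w[wsel].sum())
            se = t.residual_sd / np.sqrt(n)
            assert logv[sel].mean() == pytest.approx(oracle, abs=3.5 * se)


class TestGenerateClinical:
    def _cohort(self, n=5000, seed=1):
        traj, protos, cfg = synthetic.risk_cohort_preset(n, seed)
        return synthetic.generate_cohort(cfg, traj, protos)

    def test_alcohol_support(self):
        cohort = self._cohort(1000)
        clin = synthetic.generate_clinical(
            cohort, synthetic.default_risk_factors(), seed=2
        )
        vals = clin["alcohol_per_week"]
        assert vals.isin(range(8)).all()

    def test_null_coupling_gives_null_slope(self):
        cohort = self._cohort(5000)
        specs = {
            "glucose": synthetic.RiskFactorSpec(
                "glucose", "lognormal", math.log(100), 0.13, 0.0
            ),
            "alcohol_frequency": synthetic.RiskFactorSpec(
                "alcohol_frequency", "count7", 2.0, 1.17, 0.0
            ),
        }
        clin = synthetic.generate_clinical(cohort, specs, seed=3)
        first = cohort[cohort["scan_ordinal"] == 1].merge(clin, on="subject_id")
        r = first["latent_resid_ventricles"].to_numpy()
        for col, transform in (
            ("glucose_mg_dl", np.log),
            ("alcohol_per_week", lambda x: x),
        ):
            x = transform(first[col].to_numpy(float))
            slope = np.cov(r, x)[0, 1] / np.var(x)
            se = r.std() / (x.std() * np.sqrt(len(x)))
            assert abs(slope) < 3 * se

    def test_planted_alcohol_slope_recovered(self):
        cohort = self._cohort(40000, seed=5)
        clin = synthetic.generate_clinical(
            cohort, synthetic.default_risk_factors(), seed=6
        )
        first = cohort[cohort["scan_ordinal"] == 1].merge(clin, on="subject_id")
        r = first["latent_resid_ventricles"].to_numpy()
        x = first["alcohol_per_week"].to_numpy(float)
        slope = np.cov(r, x)[0, 1] / np.var(x)
        se = r.std() / (x.std() * np.sqrt(len(x)))
        assert slope == pytest.approx(1.24e-2, abs=3 * se)

    def test_unknown_factor_rejected(self):
        cohort = self._cohort(100)
        bad = {"smoking": synthetic.RiskFactorSpec("glucose", "lognormal", 1, 1, 0)}
        with pytest.raises(ValueError, match="smoking"):
            synthetic.generate_clinical(cohort, bad, seed=0)


def test_config_json_dict_is_serializable(presets):
    import json

    config = synthetic.default_cohort_config(10, seed=0)
    d = synthetic.config_to_json_dict(
        config, presets.trajectories, presets.protocols, presets.risk_factors
    )
    assert json.loads(json.dumps(d))["config"]["n_subjects"] == 10
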