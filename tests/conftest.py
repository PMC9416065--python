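import warnings

import pytest

from brainnorm import synthetic, volumetry

# age-clamp warnings from calibration at cohort edges are expected behaviour
warnings.filterwarnings("ignore", message=".*clamped to range")


@pytest.fixture(scope="session")
def presets():
    return synthetic.default_presets()


@pytest.fixture(scope="session")
def identity_cohort(presets):
    """Distortion-free cohort: observed volumes equal latent volumes."""
    config = synthetic.default_cohort_config(
        n_subjects=2000, seed=11, identity_bias=True
    )
    return synthetic.generate_cohort(
        config, presets.trajectories, synthetic.identity_protocols()
    )


@pytest.fixture(scope="session")
def biased_cohort(presets):
    """Cohort observed under the five-protocol mix with partial-volume bias."""
    config = synthetic.default_cohort_config(n_subjects=4000, seed=12)
    return synthetic.generate_cohort(config, presets.trajectories, presets.protocols)


@pytest.fixture(scope="session")
def ventricle_logvol(identity_cohort):
    return volumetry.log_transform(
        volumetry.proportional_normalize(identity_cohort, "ventricles")
    )
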