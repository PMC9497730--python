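import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def micro_calibration():
    from cartidiff.calibration import CalibrationCurve

    return CalibrationCurve(a=0.7531, b=1.6189, units="GL")


@pytest.fixture(scope="session")
def clinical_calibration():
    from cartidiff.calibration import CalibrationCurve

    return CalibrationCurve(a=-5.589, b=23.537, units="HU")


@pytest.fixture(scope="session")
def small_phantom():
    """A noiseless phantom pair small enough for fast unit tests."""
    from cartidiff.synthetic.phantom import build_ct_phantom_pair

    return build_ct_phantom_pair(shape=(64, 48, 32), noise_sd_hu=0.0, seed=11)


@pytest.fixture(scope="session")
def default_field():
    """Finite-bath slab simulation under the default bench conditions."""
    from cartidiff.synthetic.slab import SlabDiffusionConfig, solve_slab_diffusion

    return solve_slab_diffusion(SlabDiffusionConfig(nx=120))
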