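import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from turbistat import protocols
from turbistat import virtualrig as vr
from turbistat.calibration import CalibrationCurve

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    # curve fixtures are immutable dataclasses, safe to share across examples
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def optics():
    return vr.make_optics("S0", led_power=2)


@pytest.fixture(scope="session")
def vial():
    return vr.TrueVial("V0", glass_offset=120.0)


@pytest.fixture(scope="session")
def exact_curve(optics, vial):
    """Curve fitted to noise-free fixed-vial calibration data (same vial)."""
    return protocols.calibrate_position(optics, vial, noise=False, rng=0)


@pytest.fixture(scope="session")
def noisy_curve(optics, vial):
    return protocols.calibrate_position(optics, vial, rng=np.random.default_rng(7))


@pytest.fixture
def handmade_curve():
    """Curve with round parameters, for arithmetic-level checks."""
    return CalibrationCurve(
        sleeve_id="S9",
        vial_id="V9",
        params=(30600.0, 12000.0, 0.35, 0.18),
        raw_0_cal=41115.0,
        valid_raw_range=(33000.0, 42000.0),
        od_range=(0.0, 0.8),
        rmse_raw=0.0,
        max_od_residual=0.0,
    )
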