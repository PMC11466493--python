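import numpy as np
import pytest

from wedgecal import (
    CalibrationRange,
    ExposurePlan,
    SyntheticProfileParams,
    make_wedge_profile,
)


@pytest.fixture
def reference_profile():
    """Noise-free synthetic wedge profile at the reference condition
    (10x10 cm2 field at 10 cm depth, eps_W = 0.454)."""
    return make_wedge_profile(SyntheticProfileParams(target_drc=0.454))


@pytest.fixture
def trapezoid_profile():
    """Symmetric trapezoid: linear penumbra ramps over [13, 17] and
    [83, 87] mm, flat top at 1.  Edge midpoints at 15 and 85 mm."""
    from wedgecal import WedgeProfile

    x = np.arange(0.0, 101.0)
    v = np.interp(x, [13.0, 17.0, 83.0, 87.0], [0.0, 1.0, 1.0, 0.0])
    return WedgeProfile(x, v)


@pytest.fixture
def linear_ramp_profile():
    """In-field linear ramp 1.4 -> 0.6 between edges at +-50 mm, with
    4-mm linear penumbrae, so the 20-80 % chord is exactly computable."""
    from wedgecal import WedgeProfile

    x = np.arange(-60.0, 61.0)
    ramp = 1.0 - 0.008 * x
    v = ramp * np.interp(x, [-52.0, -48.0, 48.0, 52.0], [0.0, 1.0, 1.0, 0.0])
    return WedgeProfile(x, v)


@pytest.fixture
def four_level_plan():
    """The 4-level validation plan: CAX doses 1.6, 3, 3.5 Gy once and
    7 Gy five times, eps_W = 0.698 (15x15 cm2 at 5 cm depth)."""
    return ExposurePlan(
        CalibrationRange(1.0, 20.0),
        0.698,
        (1.6, 3.0, 3.5, 7.0, 7.0, 7.0, 7.0, 7.0),
    )
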