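import numpy as np
import pytest

from dynaqa import (
    ControlPoint,
    DynamicBeam,
    make_sliding_window_plan,
    millennium120,
)


@pytest.fixture(scope="session")
def geometry():
    return millennium120()


@pytest.fixture(scope="session")
def ramp_beam():
    """Constant-gap sliding window with a closed-form interior fluence."""
    return make_sliding_window_plan(1, "ramp", seed=0).beams[0]


@pytest.fixture(scope="session")
def random_beam():
    """Seeded smoothly modulated sliding-window beam."""
    return make_sliding_window_plan(1, "random", seed=7).beams[0]


def static_beam(tip_a_mm: float, tip_b_mm: float, total_mu: float = 100.0,
                pairs=slice(None)) -> DynamicBeam:
    """Two-control-point beam holding one rectangular aperture."""
    geometry = millennium120()
    n = geometry.n_pairs
    a = np.zeros(n)
    b = np.zeros(n)
    a[pairs] = tip_a_mm
    b[pairs] = tip_b_mm
    cps = [ControlPoint(index=f, bank_a=a.copy(), bank_b=b.copy()) for f in (0.0, 1.0)]
    return DynamicBeam(beam_id="static", control_points=cps, total_mu=total_mu)


@pytest.fixture
def open_square_beam():
    """Static 100 x 100 mm open field (central 20 pairs, tips at +-50 mm)."""
    return static_beam(-50.0, 50.0, pairs=slice(20, 40))
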