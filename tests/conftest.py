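import numpy as np
import pytest

from calscreen import WellTrace


def piecewise_reference_trace() -> WellTrace:
    """Noise-free piecewise-linear reference trace with known parameters.

    Baseline 100 AU for t < 60 s, injection drop to 90 AU at 60 s, linear
    rise to 300 AU at 120 s, linear decay to 200 AU at 360 s; sampled
    every 2 s.  Closed-form values (independent integration, frozen):
    F0 = 100, P4 = 300, P2 = 200, P3 = (300-90)/60 = 3.5,
    P5 = P6 = (200-300)/240 = -5/12, P7 = 5700 + 36000 = 41700.
    """
    t = np.arange(0.0, 361.0, 2.0)
    f = np.where(
        t < 60.0,
        100.0,
        np.where(t <= 120.0, 90.0 + 3.5 * (t - 60.0), 300.0 - (100.0 / 240.0) * (t - 120.0)),
    )
    return WellTrace(plate_id="REF", well_id="A1", time_s=t, fluorescence_au=f)


REFERENCE_EXPECTED = {
    "p1": 100.0,
    "p2": 200.0,
    "p3": 3.5,
    "p4": 300.0,
    "p5": -100.0 / 240.0,
    "p6": -100.0 / 240.0,
    "p7": 41700.0,
}


@pytest.fixture
def reference_trace() -> WellTrace:
    return piecewise_reference_trace()


@pytest.fixture
def small_screen():
    """A small deterministic synthetic screen shared across tests."""
    from calscreen import generate_screen

    return generate_screen(n_compounds=40, seed=7)
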