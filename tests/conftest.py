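import numpy as np
import pytest

from shelterchron.calcurve import make_linear_curve
from shelterchron.calibrate import RadiocarbonDate


@pytest.fixture(scope="session")
def identity_curve():
    """Identity calibration curve with no curve error: closed-form oracle."""
    return make_linear_curve(0.0, 13_000.0, 10.0, 0.0)


@pytest.fixture(scope="session")
def identity_curve_sigma5():
    """Identity curve with a 5-year curve uncertainty (the synthetic default)."""
    return make_linear_curve(0.0, 13_000.0, 10.0, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_101)


def simulate_phase_dates(rng, name, start, end, n, sigma=25.0, prefix=None):
    """Dates uniform in [end, start] measured on the identity curve."""
    prefix = prefix or name
    out = []
    for i in range(n):
        theta = rng.uniform(end, start)
        out.append(
            RadiocarbonDate(f"{prefix}-{i:02d}", float(rng.normal(theta, sigma)), sigma, stratum=name)
        )
    return out
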