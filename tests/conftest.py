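import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import releasefit as rf

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def simple_curve():
    """A short monotone release curve (power-law-like, no noise)."""
    t = np.array([10.0, 30.0, 60.0, 120.0, 240.0, 480.0])
    return rf.ReleaseCurve("demo", t, 2.0 * np.sqrt(t))


def noiseless_fixture_curve(drug, model, n_points=34):
    """Noiseless synthetic curve from one published fitted equation."""
    fx = rf.fixture(drug, model)
    grid = rf.default_time_grid(drug, model, n_points)
    spec = rf.SyntheticSpec(model, fx.params, tuple(grid), 0.0, 0, drug)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rf.generate_curve(spec)
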