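import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aequovar.assay import LuminescenceTrace, Role

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("default")


@pytest.fixture
def make_trace():
    """Trace builder with a regular grid and sensible defaults."""

    def build(signal, dt=1.0, injection_time=None, well_id="w1",
              sample_id="s1", role=Role.VARIANT, t0=0.0):
        signal = np.asarray(signal, dtype=float)
        times = t0 + dt * np.arange(signal.size)
        if injection_time is None:
            injection_time = float(times[0])
        return LuminescenceTrace(
            well_id=well_id, sample_id=sample_id, role=role,
            times=times, signal=signal, injection_time=injection_time)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
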