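import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bpvar.traces import BPTrace, CleanTrace  # noqa: E402


def make_trace(x, valid=None, dt=1.0, patient_id="p", channel="SBP"):
    x = np.asarray(x, dtype=float)
    if valid is None:
        valid = np.isfinite(x)
    t = np.arange(x.size) * dt
    return BPTrace(patient_id, channel, t, x, np.asarray(valid, bool))


def make_clean(x, valid=None, dt=1.0, **kw):
    tr = make_trace(x, valid=valid, dt=dt)
    return CleanTrace(tr.patient_id, tr.channel, tr.t, tr.x, tr.valid, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
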