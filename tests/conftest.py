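import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from teemetrics import load_anatomy, load_protocol
from teemetrics.session_log import SessionLog, ViewAttempt

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def anatomy():
    return load_anatomy()


@pytest.fixture(scope="session")
def protocol(anatomy):
    return load_protocol(anatomy=anatomy)


@pytest.fixture(scope="session")
def targets_by_id(protocol):
    return {t.view_id: t for t in protocol}


def make_attempt(view_id=1, view_name="ME 5-chamber", n=50, dt=0.1,
                 precision=None, perforated=False, **coords):
    """Constant-coordinate attempt with an optional logged precision channel.

    ``precision`` may be a scalar (held constant) or an array; coordinate
    channels default to a mid-esophageal resting state and accept scalar or
    array overrides.
    """
    base = {"depth": 30.0, "rotation": 0.0, "ante_retro": 0.0,
            "left_right": 0.0, "omniplane": 0.0}
    base.update(coords)
    chans = {}
    for name, val in base.items():
        arr = np.asarray(val, dtype=float)
        chans[name] = np.full(n, float(arr)) if arr.ndim == 0 else arr
    n = len(chans["depth"])
    if precision is not None:
        precision = np.asarray(precision, dtype=float)
        if precision.ndim == 0:
            precision = np.full(n, float(precision))
    return ViewAttempt(view_id=view_id, view_name=view_name,
                       t=np.arange(n) * dt, precision=precision,
                       perforated=perforated, **chans)


def make_session(attempts, student_id="s01", test_id=1):
    return SessionLog(student_id, test_id, list(attempts))
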