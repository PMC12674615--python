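import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import spckit as sk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def probe_schedule():
    return sk.build_probe_schedule()


@pytest.fixture(scope="session")
def precond_schedule():
    return sk.build_preconditioning_schedule()


def make_track(positions_cm, fps=25.0, px_per_cm=10.0, bodypart="body", likelihood=None):
    """Build a single-bodypart PoseTrack from an (n, 2) cm position array."""
    pos = np.asarray(positions_cm, dtype=float)
    lk = np.ones(len(pos)) if likelihood is None else np.asarray(likelihood, float)
    data = pd.DataFrame(
        {
            (bodypart, "x"): pos[:, 0] * px_per_cm,
            (bodypart, "y"): pos[:, 1] * px_per_cm,
            (bodypart, "likelihood"): lk,
        }
    )
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return sk.PoseTrack(fps=fps, px_per_cm=px_per_cm, data=data)


@pytest.fixture
def straight_track():
    """1 cm/frame along x at 10 fps -> 10 cm/s everywhere."""
    pos = np.column_stack([np.arange(11, dtype=float), np.zeros(11)])
    return make_track(pos, fps=10.0)
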