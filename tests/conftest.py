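import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colonytrack import ChamberSpec, LightSchedule, SessionRecording, Trajectory

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

START_14 = dt.datetime(2018, 1, 1, 14, 0, 0)
START_08 = dt.datetime(2018, 1, 1, 8, 0, 0)


@pytest.fixture
def chamber():
    return ChamberSpec.rectangle(240.0, 240.0, px_per_mm=0.5)


@pytest.fixture
def schedule():
    return LightSchedule.from_clock("08:00", "20:00", "08:00")


def build_session(positions: dict[str, np.ndarray], chamber=None, schedule=None,
                  start=START_14, groups=None) -> SessionRecording:
    """Session from {mouse_id: (T, 2) mm array}; fully observed."""
    chamber = chamber or ChamberSpec.rectangle(240.0, 240.0, px_per_mm=0.5)
    schedule = schedule or LightSchedule.from_clock()
    groups = groups or {}
    trajs = []
    for mid, pos in positions.items():
        pos = np.asarray(pos, float)
        trajs.append(Trajectory(mid, np.arange(len(pos)), pos[:, 0], pos[:, 1],
                                np.ones(len(pos), bool),
                                group=groups.get(mid, "GH")))
    return SessionRecording(chamber, schedule, start, trajs)


def random_walk_session(n_mice: int, T: int, seed: int, start=START_14,
                        side: float = 240.0) -> SessionRecording:
    """Independent reflected random walks, a cheap stand-in for a recording."""
    rng = np.random.default_rng(seed)
    positions = {}
    for k in range(n_mice):
        steps = rng.normal(0, 15.0, size=(T, 2))
        p = np.cumsum(steps, axis=0) + rng.uniform(40, side - 40, size=2)
        p = np.abs(p)  # reflect at 0 and at the far wall
        p = side - np.abs(side - (p % (2 * side)))
        positions[f"M{k}"] = p
    return build_session(positions, start=start)
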