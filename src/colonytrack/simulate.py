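"""Agent-based simulation of co-housed mice on a 1-Hz grid.

Each agent alternates between rest and active bouts via a per-second
Markov switch whose rates are modulated by the light/dark cycle (mice
are nocturnal: dark-phase activation is boosted).  An active agent takes
a correlated random walk (von Mises heading noise around the previous
heading, truncated-normal step length) whose heading is biased toward
the nearest cagemate with a weight given by its current sociability; the
sociability of isolation-reared phenotypes ramps up with time in the
chamber.  A resting agent whose nearest cagemate is within the
attraction radius *and is itself stationary* (resting or anaesthetised)
has its activation probability multiplied by ``rest_stickiness`` — a
low-reactive partner is easy to stay beside.  This rest-site stickiness
is what lets huddles persist once formed and lets immobile cagemates
nucleate huddles for otherwise asocial agents.  Walls reflect.
Everything is reproducible from a single seed.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .session import ChamberSpec, LightSchedule, SessionRecording, Trajectory

__all__ = ["PhenotypeParams", "SimConfig", "simulate", "preset",
           "GH_PARAMS", "SI_PARAMS", "IMMOBILE_PARAMS", "PRESET_NAMES"]


@dataclass(frozen=True)
class PhenotypeParams:
    """Behavioural parameters of one simulated mouse.

    speed_mean_mm_s   mean step length during active bouts (mm/s)
    speed_sd_frac     step-length SD as a fraction of the mean
    p_rest_to_active  baseline per-second activation probability
    p_active_to_rest  baseline per-second rest-switch probability
    circadian_amplitude  in [0, 1): dark-phase activation is scaled by
                      (1 + amplitude), light-phase by (1 - amplitude)
    sociability_0     initial heading-bias weight toward the nearest
                      cagemate, in [0, 1]
    sociability_ramp_per_h  per-hour sociability increment (capped at 1)
    heading_kappa     von Mises concentration of the heading noise
    immobile          anaesthetised agent: never moves
    """

    speed_mean_mm_s: float = 40.0
    speed_sd_frac: float = 0.2
    p_rest_to_active: float = 0.02
    p_active_to_rest: float = 0.06
    circadian_amplitude: float = 0.6
    sociability_0: float = 0.8
    sociability_ramp_per_h: float = 0.0
    heading_kappa: float = 4.0
    immobile: bool = False

    def __post_init__(self):
        if not self.immobile:
            if not (0.0 < self.p_rest_to_active < 1.0
                    and 0.0 < self.p_active_to_rest < 1.0):
                raise ValueError("switch probabilities must lie in (0, 1)")
        if not 0.0 <= self.circadian_amplitude < 1.0:
            raise ValueError("circadian_amplitude must lie in [0, 1)")
        if not 0.0 <= self.sociability_0 <= 1.0:
            raise ValueError("sociability_0 must lie in [0, 1]")


#: phenotype presets: socially-reared (fast huddling, normal activity),
#: isolation-reared (low initial sociability that ramps up, hyperactive)
#: and anaesthetised (immobile) agents.
GH_PARAMS = PhenotypeParams(speed_mean_mm_s=40.0, p_rest_to_active=0.02,
                            p_active_to_rest=0.06, circadian_amplitude=0.6,
                            sociability_0=0.2, sociability_ramp_per_h=0.0)
SI_PARAMS = PhenotypeParams(speed_mean_mm_s=60.0, p_rest_to_active=0.06,
                            p_active_to_rest=0.03, circadian_amplitude=0.6,
                            sociability_0=0.0, sociability_ramp_per_h=0.015)
IMMOBILE_PARAMS = PhenotypeParams(immobile=True, sociability_0=0.0)

PRESET_NAMES = ("GH_only", "SI_only", "mixed", "immobile_model")


@dataclass
class SimConfig:
    chamber: ChamberSpec
    schedule: LightSchedule
    start: _dt.datetime
    duration_h: float
    mice: dict[str, PhenotypeParams]
    groups: dict[str, str]
    attraction_radius_mm: float = 60.0
    #: multiplier on the activation probability of a resting agent whose
    #: nearest cagemate is within the attraction radius and stationary
    rest_stickiness: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if len(self.mice) < 2:
            raise ValueError("need at least 2 mice")
        if set(self.mice) != set(self.groups):
            raise ValueError("mice and groups must name the same ids")


@njit(cache=True)
def _step_loop(pos0, immobile, state0, heading0, speeds, vm, u_switch,
               p_act, p_rest, soc, attr_radius, stickiness,
               circle, w_or_r, h_mm):
    """Sequential 1-Hz update; all random draws are pre-generated.

    pos0 (n,2) initial positions; speeds/vm/u_switch/p_act/p_rest/soc are
    (T, n) arrays.  Returns positions of shape (T, n, 2) where row t is
    the position *at* second t (row 0 == pos0).
    """
    T, n = speeds.shape
    out = np.empty((T, n, 2))
    pos = pos0.copy()
    state = state0.copy()
    heading = heading0.copy()
    for t in range(T):
        for i in range(n):
            out[t, i, 0] = pos[i, 0]
            out[t, i, 1] = pos[i, 1]
        if t == T - 1:
            break
        for i in range(n):
            if immobile[i]:
                continue
            # nearest cagemate (positions at the start of the step)
            best = 1e18
            bj = -1
            for j in range(n):
                if j == i:
                    continue
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                d2 = dx * dx + dy * dy
                if d2 < best:
                    best = d2
                    bj = j
            near = best < attr_radius * attr_radius
            if state[i] == 0:  # resting
                pa = p_act[t, i]
                if near and (immobile[bj] or state[bj] == 0):
                    # rest-site stickiness beside a low-reactive neighbour
                    pa *= stickiness
                if u_switch[t, i] < pa:
                    state[i] = 1
                    heading[i] = heading[i] + vm[t, i]
            else:  # active
                if u_switch[t, i] < p_rest[t, i]:
                    state[i] = 0
                else:
                    w = soc[t, i]
                    hx = (1.0 - w) * math.cos(heading[i])
                    hy = (1.0 - w) * math.sin(heading[i])
                    if bj >= 0 and w > 0.0 and best > 1e-12:
                        dn = math.sqrt(best)
                        hx += w * (pos[bj, 0] - pos[i, 0]) / dn
                        hy += w * (pos[bj, 1] - pos[i, 1]) / dn
                    if hx != 0.0 or hy != 0.0:
                        heading[i] = math.atan2(hy, hx)
                    heading[i] = heading[i] + vm[t, i]
                    sp = speeds[t, i]
                    if sp < 0.0:
                        sp = 0.0
                    x = pos[i, 0] + sp * math.cos(heading[i])
                    y = pos[i, 1] + sp * math.sin(heading[i])
                    if circle:
                        r = w_or_r
                        rr = math.sqrt(x * x + y * y)
                        if rr > r:  # pull back just inside the wall, bounce
                            s = r * (1.0 - 1e-12) / rr
                            x *= s
                            y *= s
                            heading[i] = heading[i] + math.pi
                    else:
                        if x < 0.0:
                            x = -x
                            heading[i] = math.pi - heading[i]
                        elif x > w_or_r:
                            x = 2.0 * w_or_r - x
                            heading[i] = math.pi - heading[i]
                        if y < 0.0:
                            y = -y
                            heading[i] = -heading[i]
                        elif y > h_mm:
                            y = 2.0 * h_mm - y
                            heading[i] = -heading[i]
                    pos[i, 0] = x
                    pos[i, 1] = y
    return out


def simulate(config: SimConfig) -> SessionRecording:
    """Run the agent-based colony model and return an imputation-free
    (fully observed) :class:`SessionRecording`."""
    T = int(round(config.duration_h * 3600))
    ids = sorted(config.mice)
    n = len(ids)
    params = [config.mice[i] for i in ids]
    rng = np.random.default_rng(config.seed)

    ch = config.chamber
    if ch.shape == "rectangle":
        circle, w_or_r, h_mm = False, ch.width_mm, ch.height_mm
        margin = min(10.0, 0.1 * min(ch.width_mm, ch.height_mm))
        pos0 = np.column_stack([
            rng.uniform(margin, ch.width_mm - margin, n),
            rng.uniform(margin, ch.height_mm - margin, n)])
    else:
        r = ch.diameter_mm / 2.0
        circle, w_or_r, h_mm = True, r, 0.0
        rad = (r - 10.0) * np.sqrt(rng.uniform(0, 1, n))
        ang = rng.uniform(0, 2 * np.pi, n)
        pos0 = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])

    immobile = np.array([p.immobile for p in params])
    state0 = np.ones(n, dtype=np.int8)  # introduced mice start out exploring
    heading0 = rng.uniform(0, 2 * np.pi, n)

    t_arr = np.arange(T, dtype=np.int64)
    clock = (config.start.hour * 3600 + config.start.minute * 60
             + config.start.second + t_arr)
    dark = ~config.schedule.is_light(clock)

    speeds = np.empty((T, n))
    vm = np.empty((T, n))
    u_switch = rng.uniform(0, 1, size=(T, n))
    p_act = np.empty((T, n))
    p_rest = np.empty((T, n))
    soc = np.empty((T, n))
    hours = t_arr / 3600.0
    for k, p in enumerate(params):
        mean = p.speed_mean_mm_s
        speeds[:, k] = rng.normal(mean, p.speed_sd_frac * mean, size=T)
        vm[:, k] = rng.vonmises(0.0, p.heading_kappa, size=T)
        amp = p.circadian_amplitude
        mod = np.where(dark, 1.0 + amp, 1.0 - amp)
        p_act[:, k] = np.clip(p.p_rest_to_active * mod, 0.0, 1.0)
        p_rest[:, k] = np.clip(p.p_active_to_rest * np.where(dark, 1.0 - amp, 1.0 + amp),
                               0.0, 1.0)
        soc[:, k] = np.clip(p.sociability_0 + p.sociability_ramp_per_h * hours, 0.0, 1.0)

    pos = _step_loop(pos0, immobile, state0, heading0, speeds, vm, u_switch,
                     p_act, p_rest, soc, config.attraction_radius_mm,
                     config.rest_stickiness, circle, w_or_r, h_mm)

    trajs = [Trajectory(mid, t_arr, pos[:, k, 0], pos[:, k, 1],
                        np.ones(T, dtype=bool), group=config.groups[mid])
             for k, mid in enumerate(ids)]
    return SessionRecording(config.chamber, config.schedule, config.start, trajs)


# ---------------------------------------------------------------------------
# experiment presets
# ---------------------------------------------------------------------------

_DEFAULT_CHAMBER = ChamberSpec.rectangle(240.0, 240.0, px_per_mm=0.5)
_DEFAULT_START = _dt.datetime(2018, 1, 1, 14, 0, 0)  # introduction at 14:00


def preset(name: str, duration_h: float | None = None, seed: int = 0) -> SimConfig:
    """Four-mouse chamber configurations mirroring the study designs.

    GH_only / SI_only: four socially-reared or four isolation-reared mice
    observed over four days; mixed: 2 + 2 over three days; immobile_model:
    two isolation-reared subjects with two anaesthetised cagemates.
    ``duration_h`` overrides the default observation window.
    """
    schedule = LightSchedule.from_clock("08:00", "20:00", "08:00")
    if name == "GH_only":
        mice = {f"GH{i}": GH_PARAMS for i in range(1, 5)}
        groups = {m: "GH" for m in mice}
        dur = 84.0
    elif name == "SI_only":
        mice = {f"SI{i}": SI_PARAMS for i in range(1, 5)}
        groups = {m: "SI" for m in mice}
        dur = 84.0
    elif name == "mixed":
        mice = {"GH1": GH_PARAMS, "GH2": GH_PARAMS,
                "SI1": SI_PARAMS, "SI2": SI_PARAMS}
        groups = {"GH1": "GH", "GH2": "GH", "SI1": "SI", "SI2": "SI"}
        dur = 72.0
    elif name == "immobile_model":
        mice = {"SI1": SI_PARAMS, "SI2": SI_PARAMS,
                "AN1": IMMOBILE_PARAMS, "AN2": IMMOBILE_PARAMS}
        groups = {"SI1": "SI", "SI2": "SI",
                  "AN1": "ANAESTHETISED", "AN2": "ANAESTHETISED"}
        dur = 48.0
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return SimConfig(_DEFAULT_CHAMBER, schedule, _DEFAULT_START,
                     duration_h=duration_h or dur, mice=mice, groups=groups,
                     seed=seed)
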