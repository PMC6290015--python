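"""Domain types, position-table I/O, time conventions and gap imputation.

Coordinate convention: chamber millimetres, origin at the lower-left corner
for rectangular chambers or at the centre for circular chambers, with y
increasing upward.  Pixel-space sources (origin top-left, y down) are
converted by the tracking layer via ``px_per_mm`` with an explicit y-flip.

Time convention: an integer-second grid at exactly 1 Hz, ``t = 0`` at the
moment the animals are introduced.  Analysis bins are aligned to the
wall clock (the light-schedule grid), not to session start, so a session
starting mid-bin has a truncated first bin.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ChamberSpec",
    "LightSchedule",
    "Trajectory",
    "SessionRecording",
    "read_positions",
    "write_positions",
    "impute_gaps",
    "bin_index",
    "global_bin",
    "load_session_config",
    "save_session_config",
]

#: slack (mm) allowed outside the stated geometry before an input position
#: is rejected — a marker centre may slightly overhang the wall.
IN_CHAMBER_TOLERANCE_MM = 5.0

DAY_S = 86_400
GROUPS = ("GH", "SI", "ANAESTHETISED")


def _clock_seconds(value) -> int:
    """Coerce a time-of-day ('HH:MM', 'HH:MM:SS', time, int seconds) to seconds."""
    if isinstance(value, (int, np.integer)):
        s = int(value)
    elif isinstance(value, _dt.time):
        s = value.hour * 3600 + value.minute * 60 + value.second
    elif isinstance(value, _dt.datetime):
        s = value.hour * 3600 + value.minute * 60 + value.second
    elif isinstance(value, str):
        parts = [int(p) for p in value.split(":")]
        while len(parts) < 3:
            parts.append(0)
        s = parts[0] * 3600 + parts[1] * 60 + parts[2]
    else:
        raise TypeError(f"cannot interpret {value!r} as a time of day")
    if not 0 <= s < DAY_S:
        raise ValueError(f"time of day out of range: {value!r}")
    return s


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry of one experimental chamber.

    ``px_per_mm`` is only used when converting to/from camera pixel
    coordinates in the tracking layer.
    """

    shape: str  # "rectangle" | "circle"
    width_mm: float | None = None
    height_mm: float | None = None
    diameter_mm: float | None = None
    px_per_mm: float = 1.0

    def __post_init__(self):
        if self.shape == "rectangle":
            if not (self.width_mm and self.height_mm
                    and self.width_mm > 0 and self.height_mm > 0):
                raise ValueError("rectangle chamber needs positive width_mm and height_mm")
        elif self.shape == "circle":
            if not (self.diameter_mm and self.diameter_mm > 0):
                raise ValueError("circle chamber needs a positive diameter_mm")
        else:
            raise ValueError(f"unknown chamber shape {self.shape!r}")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")

    @classmethod
    def rectangle(cls, width_mm: float, height_mm: float, px_per_mm: float = 1.0):
        return cls("rectangle", width_mm=width_mm, height_mm=height_mm, px_per_mm=px_per_mm)

    @classmethod
    def circle(cls, diameter_mm: float, px_per_mm: float = 1.0):
        return cls("circle", diameter_mm=diameter_mm, px_per_mm=px_per_mm)

    def contains(self, x_mm, y_mm, tol_mm: float = 0.0):
        """Vectorised in-chamber test with ``tol_mm`` slack outside the wall."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        if self.shape == "rectangle":
            ok = ((x >= -tol_mm) & (x <= self.width_mm + tol_mm)
                  & (y >= -tol_mm) & (y <= self.height_mm + tol_mm))
        else:
            ok = np.hypot(x, y) <= self.diameter_mm / 2.0 + tol_mm
        return ok

    @property
    def frame_shape_px(self) -> tuple[int, int]:
        """(rows, cols) of a camera frame covering the chamber."""
        if self.shape == "rectangle":
            return (int(np.ceil(self.height_mm * self.px_per_mm)) + 1,
                    int(np.ceil(self.width_mm * self.px_per_mm)) + 1)
        d = int(np.ceil(self.diameter_mm * self.px_per_mm)) + 1
        return (d, d)

    def mm_to_px(self, x_mm, y_mm):
        """Chamber mm -> pixel (x_px right, y_px down, origin top-left)."""
        s = self.px_per_mm
        if self.shape == "rectangle":
            return np.asarray(x_mm) * s, (self.height_mm - np.asarray(y_mm)) * s
        r = self.diameter_mm / 2.0
        return (np.asarray(x_mm) + r) * s, (r - np.asarray(y_mm)) * s

    def px_to_mm(self, x_px, y_px):
        s = self.px_per_mm
        if self.shape == "rectangle":
            return np.asarray(x_px) / s, self.height_mm - np.asarray(y_px) / s
        r = self.diameter_mm / 2.0
        return np.asarray(x_px) / s - r, r - np.asarray(y_px) / s


@dataclass(frozen=True)
class LightSchedule:
    """12/12 light-dark schedule; the experimental day increments at
    ``day_boundary`` (conventionally lights-on)."""

    lights_on_s: int = 8 * 3600
    lights_off_s: int = 20 * 3600
    day_boundary_s: int = 8 * 3600

    def __post_init__(self):
        if not 0 <= self.lights_on_s < self.lights_off_s <= DAY_S:
            raise ValueError("require 0 <= lights_on < lights_off <= 24:00")
        if not 0 <= self.day_boundary_s < DAY_S:
            raise ValueError("day boundary must be a time of day")

    @classmethod
    def from_clock(cls, lights_on="08:00", lights_off="20:00", day_boundary="08:00"):
        return cls(_clock_seconds(lights_on), _clock_seconds(lights_off),
                   _clock_seconds(day_boundary))

    def is_light(self, clock_s):
        """Light phase is [lights_on, lights_off) on the 24-h clock."""
        c = np.asarray(clock_s) % DAY_S
        return (c >= self.lights_on_s) & (c < self.lights_off_s)

    @property
    def light_seconds(self) -> int:
        return self.lights_off_s - self.lights_on_s


@dataclass
class Trajectory:
    """One mouse's time-ordered 1-Hz position samples.

    ``observed`` marks samples that were actually identified; imputed
    samples carry the last observed coordinates with ``observed=False``.
    Gap markers (not yet imputed) have NaN coordinates.
    """

    mouse_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    observed: np.ndarray
    group: str = "GH"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.observed) == n):
            raise ValueError("t, x, y, observed must have equal length")
        if n and np.any(np.diff(self.t) <= 0):
            raise ValueError(f"trajectory {self.mouse_id}: t must be strictly increasing")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def gapless(self) -> bool:
        return len(self.t) > 0 and bool(np.all(np.diff(self.t) == 1)) \
            and not np.any(np.isnan(self.x)) and not np.any(np.isnan(self.y))

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def impute_gaps(traj: Trajectory) -> Trajectory:
    """Fill every missing second with the most recent observed position.

    Implements last-observation-carried-forward over the full span
    ``[t_first, t_last]``: when the marker is not identified at a second,
    the position from when it was last identified is carried, flagged
    ``observed=False``.  Idempotent; observed samples are never altered.

    Raises ``ValueError`` on an empty trajectory or when the first sample
    is itself unobserved (nothing to carry forward — untrackable prefix).
    """
    if len(traj) == 0:
        raise ValueError(f"trajectory {traj.mouse_id}: empty, cannot impute")
    obs = traj.observed & ~np.isnan(traj.x) & ~np.isnan(traj.y)
    if not obs[0]:
        raise ValueError(
            f"trajectory {traj.mouse_id}: leading gap (first sample unobserved); "
            "the untrackable prefix must be trimmed upstream")
    t0, t1 = int(traj.t[0]), int(traj.t[-1])
    n = t1 - t0 + 1
    full_t = np.arange(t0, t1 + 1, dtype=np.int64)
    full_obs = np.zeros(n, dtype=bool)
    full_obs[traj.t - t0] = obs
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    x[traj.t[obs] - t0] = traj.x[obs]
    y[traj.t[obs] - t0] = traj.y[obs]
    # forward fill from the last observed sample
    idx = np.where(full_obs, np.arange(n), 0)
    np.maximum.accumulate(idx, out=idx)
    x = x[np.where(full_obs, np.arange(n), idx)]
    y = y[np.where(full_obs, np.arange(n), idx)]
    return Trajectory(traj.mouse_id, full_t, x, y, full_obs, traj.group)


def bin_index(t, bin_minutes: int, schedule: LightSchedule, start_clock):
    """Map session seconds to clock-aligned ``(day, phase, bin)`` triples.

    ``day`` is 1-based and increments at the schedule's day boundary;
    ``phase`` is 0 for light, 1 for dark; ``bin`` is the 0-based bin index
    within the current phase (24 thirty-minute bins per 12-h phase).
    ``bin_minutes`` must divide the 720-minute phase so that no bin
    straddles a lights-on/lights-off boundary.

    Accepts scalars or arrays; returns numpy arrays (or scalars for scalar
    input).
    """
    if 720 % bin_minutes != 0:
        raise ValueError(f"bin_minutes={bin_minutes} does not divide the 720-min phase")
    t_arr = np.asarray(t)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    start_s = _clock_seconds(start_clock)
    abs_s = start_s + t_arr.astype(np.int64)  # seconds since midnight of day 1
    clock = abs_s % DAY_S
    day = 1 + (abs_s - schedule.day_boundary_s) // DAY_S \
        - (start_s - schedule.day_boundary_s) // DAY_S
    light = schedule.is_light(clock)
    phase = np.where(light, 0, 1)
    phase_start = np.where(light, schedule.lights_on_s, schedule.lights_off_s)
    into_phase = (clock - phase_start) % DAY_S
    b = into_phase // (bin_minutes * 60)
    if t_arr.ndim == 0:
        return int(day), int(phase), int(b)
    return day.astype(int), phase.astype(int), b.astype(int)


def global_bin(t, bin_minutes: int, start_clock):
    """0-based clock-aligned bin index counted from session start.

    Bin edges sit on the wall-clock grid (multiples of ``bin_minutes``
    past midnight), so the first bin of a session starting mid-bin is
    truncated.
    """
    if DAY_S % (bin_minutes * 60) != 0:
        raise ValueError(f"bin_minutes={bin_minutes} does not divide the day")
    start_s = _clock_seconds(start_clock)
    abs_s = start_s + np.asarray(t, dtype=np.int64)
    w = bin_minutes * 60
    g = abs_s // w - start_s // w
    return int(g) if np.ndim(t) == 0 else g.astype(int)


@dataclass
class SessionRecording:
    """A set of co-housed trajectories sharing one chamber, schedule and clock."""

    chamber: ChamberSpec
    schedule: LightSchedule
    start: _dt.datetime
    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self):
        ids = [tr.mouse_id for tr in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("mouse_ids must be unique within a session")
        if not isinstance(self.start, _dt.datetime):
            raise TypeError("start must be a datetime (date + time of day)")

    # -- convenience accessors -------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [tr.mouse_id for tr in self.trajectories]

    @property
    def groups(self) -> dict[str, str]:
        return {tr.mouse_id: tr.group for tr in self.trajectories}

    @property
    def start_clock_s(self) -> int:
        return _clock_seconds(self.start)

    def trajectory(self, mouse_id: str) -> Trajectory:
        for tr in self.trajectories:
            if tr.mouse_id == mouse_id:
                return tr
        raise KeyError(mouse_id)

    @property
    def aligned(self) -> bool:
        """True when every trajectory is gapless on one common t-grid."""
        if not self.trajectories:
            return False
        t0 = self.trajectories[0].t
        return all(tr.gapless and len(tr.t) == len(t0) and tr.t[0] == t0[0]
                   for tr in self.trajectories)

    @property
    def t(self) -> np.ndarray:
        if not self.aligned:
            raise ValueError("session is not aligned; call .impute() first")
        return self.trajectories[0].t

    @property
    def duration_s(self) -> int:
        return int(max(tr.t[-1] for tr in self.trajectories)) + 1

    def impute(self) -> "SessionRecording":
        """Impute every trajectory and verify a common [0, T] span."""
        trajs = [impute_gaps(tr) for tr in self.trajectories]
        spans = {(int(tr.t[0]), int(tr.t[-1])) for tr in trajs}
        if len(spans) > 1:
            raise ValueError(f"trajectories cover different spans after imputation: {spans}")
        return replace(self, trajectories=trajs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.trajectories:
            rows.append(pd.DataFrame({
                "t_s": tr.t, "mouse_id": tr.mouse_id,
                "x_mm": tr.x, "y_mm": tr.y,
                "observed": tr.observed.astype(int),
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# position-table I/O
# ---------------------------------------------------------------------------

def read_positions(path, chamber: ChamberSpec, schedule: LightSchedule,
                   start: _dt.datetime, groups: dict[str, str] | None = None,
                   tol_mm: float = IN_CHAMBER_TOLERANCE_MM) -> SessionRecording:
    """Read a per-second per-mouse position CSV into a :class:`SessionRecording`.

    Expected header ``t_s,mouse_id,x_mm,y_mm,observed`` (``observed`` in
    {0,1}, optional, default 1).  Rows with a missing coordinate become
    unobserved gap markers.  Duplicate ``(t_s, mouse_id)`` rows and
    positions more than ``tol_mm`` outside the chamber are rejected with
    the offending row number (1-based, counting the header as row 1).
    """
    df = pd.read_csv(path, dtype={"mouse_id": str})
    required = {"t_s", "mouse_id", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"positions CSV missing columns: {sorted(missing)}")
    if "observed" not in df.columns:
        df["observed"] = 1
    df["observed"] = df["observed"].fillna(1).astype(int)
    if (df["t_s"] < 0).any() or not np.issubdtype(df["t_s"].dtype, np.integer):
        if not np.allclose(df["t_s"], np.round(df["t_s"])):
            raise ValueError("t_s must be non-negative integers (1 Hz grid)")
        df["t_s"] = df["t_s"].round().astype(np.int64)
        if (df["t_s"] < 0).any():
            raise ValueError("t_s must be non-negative")

    dup = df.duplicated(subset=["t_s", "mouse_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # header is row 1
        raise ValueError(f"duplicate (t_s, mouse_id) at CSV row {row}")

    has_pos = df["x_mm"].notna() & df["y_mm"].notna()
    inside = np.ones(len(df), dtype=bool)
    inside[has_pos.to_numpy()] = chamber.contains(
        df.loc[has_pos, "x_mm"], df.loc[has_pos, "y_mm"], tol_mm=tol_mm)
    if not inside.all():
        row = int(np.flatnonzero(~inside)[0]) + 2
        raise ValueError(f"position outside chamber (>{tol_mm} mm slack) at CSV row {row}")

    groups = groups or {}
    trajs = []
    for mid, sub in df.groupby("mouse_id", sort=True):
        sub = sub.sort_values("t_s", kind="stable")
        obs = sub["observed"].to_numpy(dtype=bool) \
            & sub["x_mm"].notna().to_numpy() & sub["y_mm"].notna().to_numpy()
        trajs.append(Trajectory(
            str(mid), sub["t_s"].to_numpy(), sub["x_mm"].to_numpy(dtype=float),
            sub["y_mm"].to_numpy(dtype=float), obs,
            group=groups.get(str(mid), "GH")))
    return SessionRecording(chamber, schedule, start, trajs)


def write_positions(session: SessionRecording, path) -> None:
    """Write the standard positions CSV (UTF-8, '.' decimal separator)."""
    session.to_frame().to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# session config I/O
# ---------------------------------------------------------------------------

def _chamber_to_dict(c: ChamberSpec) -> dict:
    d = {"shape": c.shape, "px_per_mm": c.px_per_mm}
    if c.shape == "rectangle":
        d.update(width_mm=c.width_mm, height_mm=c.height_mm)
    else:
        d.update(diameter_mm=c.diameter_mm)
    return d


def load_session_config(path):
    """Load chamber/schedule/start/groups from a YAML (or JSON) config."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    ch = cfg["chamber"]
    chamber = ChamberSpec(ch["shape"], ch.get("width_mm"), ch.get("height_mm"),
                          ch.get("diameter_mm"), ch.get("px_per_mm", 1.0))
    sc = cfg.get("schedule", {})
    schedule = LightSchedule.from_clock(sc.get("lights_on", "08:00"),
                                        sc.get("lights_off", "20:00"),
                                        sc.get("day_boundary", "08:00"))
    start = cfg["start"]
    if isinstance(start, str):
        start = _dt.datetime.fromisoformat(start)
    groups = {str(k): str(v) for k, v in (cfg.get("groups") or {}).items()}
    return chamber, schedule, start, groups


def save_session_config(path, chamber: ChamberSpec, schedule: LightSchedule,
                        start: _dt.datetime, groups: dict[str, str]) -> None:
    def hhmm(s):
        return f"{s // 3600:02d}:{s % 3600 // 60:02d}"
    cfg = {
        "chamber": _chamber_to_dict(chamber),
        "schedule": {"lights_on": hhmm(schedule.lights_on_s),
                     "lights_off": hhmm(schedule.lights_off_s),
                     "day_boundary": hhmm(schedule.day_boundary_s)},
        "start": start.isoformat(sep=" "),
        "groups": groups,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
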