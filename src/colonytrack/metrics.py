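"""Social-proximity and activity metrics on imputed 1-Hz trajectories.

The operators implement the standard social-proximity battery for
group-housed rodents: per-second inter-individual distances, approach
events into a 60-mm interaction area, interaction durations, huddling
(mean pair distance < 60 mm over a 30-min bin), locomotor activity and
between-mouse activity correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import SessionRecording, Trajectory, bin_index, global_bin

__all__ = [
    "pair_key",
    "DistanceSeries",
    "ApproachEvent",
    "HuddleSeries",
    "HuddleLatency",
    "ActivitySeries",
    "distance_series",
    "mean_distance_binned",
    "detect_approaches",
    "approach_counts",
    "duration_class_counts",
    "detect_huddles",
    "huddle_latency",
    "huddle_percentage",
    "huddle_percentages",
    "huddle_order",
    "activity_series",
    "activity_binned",
    "activity_correlation",
]

#: radius (mm) of the social interaction area around each mouse
INTERACTION_RADIUS_MM = 60.0
#: bin width (minutes) over which huddling is evaluated
HUDDLE_BIN_MINUTES = 30
#: seconds looked back before an approach onset to decide the approacher
APPROACH_LOOKBACK_S = 3


def pair_key(id_a: str, id_b: str) -> tuple[str, str]:
    """Canonical unordered pair: lexicographically sorted id tuple."""
    if id_a == id_b:
        raise ValueError("a pair needs two distinct mice")
    return (id_a, id_b) if id_a < id_b else (id_b, id_a)


@dataclass
class DistanceSeries:
    pair: tuple[str, str]
    t: np.ndarray
    d_mm: np.ndarray


@dataclass
class ApproachEvent:
    """One sub-radius episode for a pair.

    The episode spans ``[t_onset, t_end)``: the pair distance is below the
    radius throughout and at ``t_end`` it is at/above the radius again
    (or the session ended, in which case ``truncated`` is set).  The
    approacher is the pair member with the longer path over the
    ``lookback`` seconds before onset; on an exact tie
    ``approacher_defined`` is False and the lexicographically smaller id
    is recorded.
    """

    pair: tuple[str, str]
    t_onset: int
    t_end: int
    approacher: str
    approached: str
    approacher_defined: bool = True
    truncated: bool = False

    @property
    def duration_s(self) -> int:
        return self.t_end - self.t_onset


@dataclass
class HuddleSeries:
    """Per-pair clock-aligned 30-min bins with mean distance and huddle flag."""

    pair: tuple[str, str]
    bins: pd.DataFrame  # columns: gbin, day, phase, bin, n_s, mean_d_mm, is_huddle
    bin_minutes: int = HUDDLE_BIN_MINUTES


@dataclass
class HuddleLatency:
    """Latency to first huddle, end-of-bin convention (bin k -> 0.5*(k+1) h).

    If no bin ever qualified, ``censored`` is True and ``hours`` holds the
    total observed time.
    """

    hours: float
    censored: bool = False


@dataclass
class ActivitySeries:
    mouse_id: str
    t: np.ndarray       # seconds (>= 1; displacement from t-1 to t)
    v_mm_s: np.ndarray


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_series(session: SessionRecording) -> dict[tuple[str, str], DistanceSeries]:
    """Per-second Euclidean distance for every unordered pair."""
    if not session.aligned:
        raise ValueError("trajectories must be imputed/aligned before computing distances")
    t = session.t
    out: dict[tuple[str, str], DistanceSeries] = {}
    trajs = session.trajectories
    for i in range(len(trajs)):
        for j in range(i + 1, len(trajs)):
            a, b = trajs[i], trajs[j]
            d = np.hypot(a.x - b.x, a.y - b.y)
            out[pair_key(a.mouse_id, b.mouse_id)] = DistanceSeries(
                pair_key(a.mouse_id, b.mouse_id), t, d)
    return out


def _binned_mean(t: np.ndarray, values: np.ndarray, session: SessionRecording,
                 bin_minutes: int) -> pd.DataFrame:
    """Mean of a per-second series over clock-aligned bins."""
    g = global_bin(t, bin_minutes, session.start)
    day, phase, b = bin_index(t, bin_minutes, session.schedule, session.start)
    df = pd.DataFrame({"gbin": g, "day": day, "phase": phase, "bin": b, "v": values})
    out = (df.groupby(["gbin", "day", "phase", "bin"], as_index=False)
             .agg(n_s=("v", "size"), mean=("v", "mean")))
    return out.sort_values("gbin", ignore_index=True)


def mean_distance_binned(series: DistanceSeries, session: SessionRecording,
                         bin_minutes: int = HUDDLE_BIN_MINUTES) -> pd.DataFrame:
    """Mean inter-individual distance per clock-aligned bin.

    Partial first/last bins are averaged over the seconds available.
    """
    if len(series.t) == 0:
        raise ValueError("empty distance series")
    out = _binned_mean(series.t, series.d_mm, session, bin_minutes)
    return out.rename(columns={"mean": "mean_d_mm"})


# ---------------------------------------------------------------------------
# approaches and interaction durations
# ---------------------------------------------------------------------------

def _lookback_path(traj: Trajectory, onset_idx: int, lookback: int) -> float:
    """Path length over the ``lookback`` seconds before onset.

    Uses up to ``lookback + 1`` samples; a displacement step touching an
    imputed sample contributes zero (a carried-forward position is not
    locomotion).
    """
    lo = max(0, onset_idx - lookback)
    if lo == onset_idx:
        return 0.0
    dx = np.diff(traj.x[lo:onset_idx + 1])
    dy = np.diff(traj.y[lo:onset_idx + 1])
    step_ok = traj.observed[lo:onset_idx] & traj.observed[lo + 1:onset_idx + 1]
    return float(np.sum(np.hypot(dx, dy) * step_ok))


def detect_approaches(series: DistanceSeries, session: SessionRecording,
                      radius_mm: float = INTERACTION_RADIUS_MM,
                      lookback_s: int = APPROACH_LOOKBACK_S) -> list[ApproachEvent]:
    """Segment the below-radius seconds of a pair into approach events.

    An onset is a downward crossing: ``d(t) < radius`` with
    ``d(t-1) >= radius`` (exactly-at-radius counts as outside the
    interaction area).  The episode runs until the first second with
    ``d >= radius`` or the session end (``truncated``).  The events
    partition ``{t : d(t) < radius}`` into disjoint ``[t_onset, t_end)``
    intervals, except for a run already inside the area at the first
    sample — the pair never *became* closer than the radius, so no event
    is emitted (a stationary close pair yields huddles, not approaches).
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    below = series.d_mm < radius_mm
    if not below.any():
        return []
    a_id, b_id = series.pair
    ta, tb = session.trajectory(a_id), session.trajectory(b_id)
    t0 = int(series.t[0])
    edges = np.diff(below.astype(np.int8))
    onsets = list(np.flatnonzero(edges == 1) + 1)
    ends = [int(e) for e in np.flatnonzero(edges == -1) + 1]
    if below[0]:  # initial run: no crossing, drop its end marker
        if ends:
            ends.pop(0)
    truncated_last = below[-1]
    if truncated_last and len(ends) < len(onsets):
        ends.append(len(below))
    events = []
    for i0, i1 in zip(onsets, ends):
        pa = _lookback_path(ta, i0, lookback_s)
        pb = _lookback_path(tb, i0, lookback_s)
        if pa == pb:
            approacher, defined = a_id, False
        elif pa > pb:
            approacher, defined = a_id, True
        else:
            approacher, defined = b_id, True
        approached = b_id if approacher == a_id else a_id
        events.append(ApproachEvent(
            series.pair, t0 + i0, t0 + i1, approacher, approached,
            approacher_defined=defined,
            truncated=(i1 == len(below) and truncated_last)))
    return events


def approach_counts(events: list[ApproachEvent], session: SessionRecording,
                    bin_minutes: int = 30) -> pd.DataFrame:
    """Mean approach counts per clock-aligned bin and ordered group direction.

    A direction is the ordered pair (approacher group -> approached
    group).  The mean is the event count divided by the number of
    possible ordered mouse pairs with those group labels in the chamber,
    the per-direction normalisation used for chamber-level approach
    rates.
    """
    groups = session.groups
    ids = list(groups)
    n_pairs: dict[tuple[str, str], int] = {}
    for i in ids:
        for j in ids:
            if i != j:
                key = (groups[i], groups[j])
                n_pairs[key] = n_pairs.get(key, 0) + 1
    for ev in events:
        if ev.approacher not in groups or ev.approached not in groups:
            raise ValueError(f"event references unknown mouse: {ev}")
    T = session.duration_s
    all_bins = np.unique(global_bin(np.arange(T), bin_minutes, session.start))
    rows = []
    onset_bins = {}
    for ev in events:
        g = global_bin(ev.t_onset, bin_minutes, session.start)
        d = (groups[ev.approacher], groups[ev.approached])
        onset_bins[(g, d)] = onset_bins.get((g, d), 0) + 1
    for g in all_bins:
        for d, npairs in sorted(n_pairs.items()):
            cnt = onset_bins.get((int(g), d), 0)
            rows.append({"gbin": int(g), "direction": f"{d[0]}to{d[1]}",
                         "n_events": cnt, "n_possible_pairs": npairs,
                         "mean_per_pair": cnt / npairs})
    return pd.DataFrame(rows)


def duration_class_counts(events: list[ApproachEvent],
                          thresholds_s: tuple[float, float] = (2, 3)) -> tuple[int, int, int]:
    """Partition episode durations into (< lo, [lo, hi], > hi) counts."""
    lo, hi = thresholds_s
    d = np.array([ev.duration_s for ev in events], dtype=float)
    return (int(np.sum(d < lo)), int(np.sum((d >= lo) & (d <= hi))), int(np.sum(d > hi)))


# ---------------------------------------------------------------------------
# huddling
# ---------------------------------------------------------------------------

def detect_huddles(series: DistanceSeries, session: SessionRecording,
                   radius_mm: float = INTERACTION_RADIUS_MM,
                   bin_minutes: int = HUDDLE_BIN_MINUTES) -> HuddleSeries:
    """Flag clock-aligned bins whose mean pair distance is strictly below
    the radius as huddle bins."""
    binned = mean_distance_binned(series, session, bin_minutes)
    binned["is_huddle"] = binned["mean_d_mm"] < radius_mm
    return HuddleSeries(series.pair, binned, bin_minutes)


def huddle_latency(hs: HuddleSeries) -> HuddleLatency:
    """Hours from introduction to the end of the first huddle bin.

    Bins are counted from session start (0-based, clock-aligned grid);
    the k-th bin maps to ``(k + 1) * bin_minutes / 60`` hours.  Never-
    huddling pairs return a censored latency carrying the total observed
    hours.
    """
    b = hs.bins
    if len(b) == 0:
        raise ValueError("empty huddle series")
    hit = b.loc[b["is_huddle"]]
    hours_per_bin = hs.bin_minutes / 60.0
    if hit.empty:
        total_h = float(b["n_s"].sum()) / 3600.0
        return HuddleLatency(total_h, censored=True)
    first_gbin = int(hit["gbin"].iloc[0]) - int(b["gbin"].iloc[0])
    return HuddleLatency((first_gbin + 1) * hours_per_bin, censored=False)


def huddle_percentage(hs: HuddleSeries, day: int, phase: int) -> tuple[float, bool]:
    """Percent of a 12-h phase spent huddling: 100 x huddle bins / 24.

    Returns ``(percent, partial)``; ``partial`` flags a phase with fewer
    bins present than a full 12 h worth.
    """
    per_phase = 720 // hs.bin_minutes
    b = hs.bins
    sel = b[(b["day"] == day) & (b["phase"] == phase)]
    full = len(sel) == per_phase and bool((sel["n_s"] == hs.bin_minutes * 60).all())
    pct = 100.0 * float(sel["is_huddle"].sum()) / per_phase
    return pct, not full


def huddle_percentages(hs: HuddleSeries) -> pd.DataFrame:
    """Huddle percentage for every (day, phase) present in the series."""
    rows = []
    for (day, phase), _ in hs.bins.groupby(["day", "phase"]):
        pct, partial = huddle_percentage(hs, int(day), int(phase))
        rows.append({"day": int(day), "phase": int(phase),
                     "huddle_pct": pct, "partial": partial})
    return pd.DataFrame(rows).sort_values(["day", "phase"], ignore_index=True)


def huddle_order(huddles: dict[tuple[str, str], HuddleSeries]) -> dict[tuple[str, str], str]:
    """Rank pairs in a chamber by first-huddle bin into categories
    {'first', 'intermediate', 'last'}.

    Ties share the earlier category (dense ranking); pairs that never
    huddled rank after all huddling pairs.  Raises if no pair huddled.
    """
    firsts = {}
    never = []
    for pair, hs in huddles.items():
        lat = huddle_latency(hs)
        if lat.censored:
            never.append(pair)
        else:
            firsts[pair] = lat.hours
    if not firsts:
        raise ValueError("no pair ever huddled; order undefined")
    order_vals = sorted(set(firsts.values()))
    rank = {pair: order_vals.index(v) for pair, v in firsts.items()}
    max_rank = max(rank.values()) + (1 if never else 0)
    for pair in never:
        rank[pair] = max_rank
    out = {}
    for pair, r in rank.items():
        if r == 0:
            out[pair] = "first"
        elif r == max_rank and max_rank > 0:
            out[pair] = "last"
        else:
            out[pair] = "intermediate"
    return out


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def activity_series(traj: Trajectory) -> ActivitySeries:
    """Per-second locomotor activity: displacement between consecutive
    samples (mm/s), computed on the imputed positions."""
    if not traj.gapless:
        raise ValueError("trajectory must be imputed before computing activity")
    v = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return ActivitySeries(traj.mouse_id, traj.t[1:], v)


def activity_binned(series: ActivitySeries, session: SessionRecording,
                    bin_minutes: int = 30) -> pd.DataFrame:
    """Mean activity per clock-aligned bin, in mm/s and cm/min (x6)."""
    out = _binned_mean(series.t, series.v_mm_s, session, bin_minutes)
    out = out.rename(columns={"mean": "mean_mm_s"})
    out["mean_cm_min"] = out["mean_mm_s"] * 6.0
    return out


def activity_correlation(session: SessionRecording, bin_minutes: int = 5,
                         phase: int = 0, days: list[int] | None = None,
                         min_bins: int = 3) -> pd.DataFrame:
    """Pearson correlation of per-bin mean activity between every pair.

    Activity is binned over ``bin_minutes`` (default 5) and restricted to
    one phase (default light) and optionally a set of days.  Returns a
    symmetric id-indexed matrix with unit diagonal; a mouse with zero
    activity variance yields NaN (undefined), not 0.
    """
    vecs = {}
    for tr in session.trajectories:
        b = activity_binned(activity_series(tr), session, bin_minutes)
        b = b[b["phase"] == phase]
        if days is not None:
            b = b[b["day"].isin(days)]
        vecs[tr.mouse_id] = b.set_index("gbin")["mean_mm_s"]
    common = None
    for v in vecs.values():
        common = v.index if common is None else common.intersection(v.index)
    if common is None or len(common) < min_bins:
        raise ValueError(f"need at least {min_bins} {bin_minutes}-min bins in the "
                         "selected phase window")
    ids = session.ids
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b_ in ids[i + 1:]:
            x = vecs[a].loc[common].to_numpy()
            y = vecs[b_].loc[common].to_numpy()
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            mat.loc[a, b_] = mat.loc[b_, a] = r
    return mat
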