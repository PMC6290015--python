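"""Marker-based identification of glyph-tagged agents in frame stacks.

A desk-scale re-implementation of the identification core of a
pattern-matching multi-animal positioning system: each animal carries a
unique bright glyph on a dark back tag; every frame is searched for each
glyph by zero-normalised cross-correlation (ZNCC), matched at four
rotations; identification is memoryless per frame (no motion model), so
an identity is re-acquired immediately when its glyph reappears, and
frames where a glyph is not found are filled by last-observation
imputation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.feature import match_template

from .session import ChamberSpec, LightSchedule, SessionRecording, Trajectory

__all__ = [
    "GlyphTemplate",
    "FrameStack",
    "Detection",
    "make_glyph_templates",
    "make_occlusion_schedule",
    "render_session",
    "identify_frame",
    "track_stack",
    "detection_rate",
    "save_stack",
    "load_stack",
    "save_templates",
    "load_templates",
]

#: default ZNCC acceptance threshold
MATCH_THRESHOLD = 0.7
#: rotations (multiples of 90 degrees) tried for every template
ROTATIONS = (0, 1, 2, 3)


@dataclass
class GlyphTemplate:
    """A small square bright-on-dark intensity pattern identifying one mouse."""

    mouse_id: str
    image: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or self.image.shape[0] != self.image.shape[1]:
            raise ValueError("glyph templates must be square 2-D arrays")


@dataclass
class Detection:
    t: int
    mouse_id: str
    x_px: float
    y_px: float
    score: float
    found: bool


@dataclass
class FrameStack:
    """Ordered frames (one per second) with optional ground truth.

    ``ground_truth`` columns: t_s, mouse_id, x_px, y_px, visible,
    overlapped.  Chamber/schedule/start metadata travel with the stack so
    tracking output can be expressed in chamber mm on the session clock.
    """

    frames: np.ndarray  # (T, H, W) in [0, 1]
    chamber: ChamberSpec
    schedule: LightSchedule
    start: "object"
    ground_truth: pd.DataFrame | None = None
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("frame intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# template generation
# ---------------------------------------------------------------------------

def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float(np.sum(a * b) / den) if den > 0 else 0.0


def _max_shifted_corr(canvas_glyph: np.ndarray, probe: np.ndarray) -> float:
    """Peak ZNCC of ``probe`` (at all 4 rotations) against ``canvas_glyph``
    stamped alone on a dark field — covers every relative shift, including
    partial overlaps against the background."""
    tw = canvas_glyph.shape[0]
    canvas = np.zeros((3 * tw, 3 * tw))
    canvas[tw:2 * tw, tw:2 * tw] = canvas_glyph
    return max(float(match_template(canvas, np.rot90(probe, k),
                                    pad_input=True).max())
               for k in ROTATIONS)


def make_glyph_templates(mouse_ids, size: int = 16, seed: int = 0,
                         max_cross_corr: float = 0.55,
                         max_tries: int = 500) -> list[GlyphTemplate]:
    """Generate pairwise-distinct random block glyphs, one per mouse.

    Each glyph is a coarse random binary block pattern (bright blocks on
    a dark tag) upsampled to ``size``.  Candidates are rejected until
    their ZNCC against every already-accepted glyph stays below
    ``max_cross_corr`` over *all* relative shifts and 90-degree rotations
    (partial overlaps against the dark background included), so an absent
    glyph can never be confused with a present one at the default
    matching threshold.
    """
    rng = np.random.default_rng(seed)
    blocks = max(4, size // 2)  # 2-px blocks: printable yet high-entropy
    done: list[GlyphTemplate] = []
    for mid in sorted(mouse_ids):
        for _ in range(max_tries):
            coarse = rng.uniform(0, 1, (blocks, blocks)) < 0.5
            img = np.kron(coarse, np.ones((size // blocks + 1, size // blocks + 1)))
            img = img[:size, :size].astype(float)
            img = 0.15 + 0.8 * img  # dark tag background, bright glyph
            ok = all(_max_shifted_corr(t.image, img) < max_cross_corr
                     and _max_shifted_corr(img, t.image) < max_cross_corr
                     for t in done)
            # a glyph must not resemble its own rotations either, or the
            # rotation search could anchor on the wrong orientation
            ok = ok and all(_zncc(img, np.rot90(img, k)) < max_cross_corr
                            for k in (1, 2, 3))
            if ok:
                done.append(GlyphTemplate(mid, img))
                break
        else:
            raise RuntimeError(f"could not draw a distinct glyph for {mid!r}")
    return done


def make_occlusion_schedule(n_frames: int, mouse_ids, fraction: float,
                            seed: int = 0, protect_first: bool = True) -> pd.DataFrame:
    """Random per-(frame, mouse) visibility with an exact occluded count.

    Exactly ``round(fraction * n_frames)`` frames are occluded per mouse
    (drawn without replacement, never frame 0 when ``protect_first``), so
    the expected detection rate on clean frames is exactly
    ``1 - fraction``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_occ = int(round(fraction * n_frames))
    for mid in sorted(mouse_ids):
        lo = 1 if protect_first else 0
        if n_occ > n_frames - lo:
            raise ValueError("occlusion fraction too high for the stack length")
        occ = rng.choice(np.arange(lo, n_frames), size=n_occ, replace=False)
        vis = np.ones(n_frames, dtype=bool)
        vis[occ] = False
        rows.append(pd.DataFrame({"t_s": np.arange(n_frames), "mouse_id": mid,
                                  "visible": vis}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# rendering (camera stand-in for fixtures and validation)
# ---------------------------------------------------------------------------

def render_session(session: SessionRecording, templates: list[GlyphTemplate],
                   occlusion: pd.DataFrame | None = None,
                   noise_sd: float = 0.0, seed: int = 0) -> FrameStack:
    """Stamp each visible glyph at its trajectory position on dark frames.

    Positions are converted from chamber mm to pixels (origin top-left,
    y down) and rounded to the nearest pixel; additive Gaussian noise of
    ``noise_sd`` is applied and intensities clipped to [0, 1].  Glyph
    stamps closer than one template width are rendered anyway but flagged
    ``overlapped`` in the ground truth (animals piling up).
    """
    if not session.aligned:
        session = session.impute()
    by_id = {t.mouse_id: t for t in templates}
    if set(by_id) != set(session.ids):
        raise ValueError("need exactly one template per trajectory")
    tw = templates[0].image.shape[0]
    if any(t.image.shape != (tw, tw) for t in templates):
        raise ValueError("all templates must share dimensions")
    H, W = session.chamber.frame_shape_px
    T = len(session.t)
    vis = {}
    if occlusion is not None:
        for mid, sub in occlusion.groupby("mouse_id"):
            v = np.ones(T, dtype=bool)
            v[sub["t_s"].to_numpy()] = sub["visible"].to_numpy(dtype=bool)
            vis[str(mid)] = v
    rng = np.random.default_rng(seed)
    frames = np.zeros((T, H, W))
    gt_rows = []
    centres = {}
    for tr in session.trajectories:
        cx, cy = session.chamber.mm_to_px(tr.x, tr.y)
        centres[tr.mouse_id] = (np.rint(cx).astype(int), np.rint(cy).astype(int))
    ids = session.ids
    half = tw // 2
    for t in range(T):
        pts = {}
        for mid in ids:
            if mid in vis and not vis[mid][t]:
                continue
            pts[mid] = (centres[mid][0][t], centres[mid][1][t])
        for mid, (px, py) in pts.items():
            r0, c0 = py - half, px - half
            r1, c1 = r0 + tw, c0 + tw
            fr0, fc0 = max(r0, 0), max(c0, 0)
            fr1, fc1 = min(r1, H), min(c1, W)
            if fr1 <= fr0 or fc1 <= fc0:
                continue
            tmpl = by_id[mid].image[fr0 - r0:fr1 - r0, fc0 - c0:fc1 - c0]
            region = frames[t, fr0:fr1, fc0:fc1]
            np.maximum(region, tmpl, out=region)
        for mid in ids:
            visible = mid in pts
            px, py = centres[mid][0][t], centres[mid][1][t]
            overlapped = visible and any(
                o != mid and abs(pts[o][0] - px) < tw and abs(pts[o][1] - py) < tw
                for o in pts)
            gt_rows.append((t, mid, px, py, visible, overlapped))
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)
    np.clip(frames, 0.0, 1.0, out=frames)
    gt = pd.DataFrame(gt_rows, columns=["t_s", "mouse_id", "x_px", "y_px",
                                        "visible", "overlapped"])
    return FrameStack(frames, session.chamber, session.schedule, session.start,
                      ground_truth=gt, groups=session.groups)


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

def identify_frame(frame: np.ndarray, templates: list[GlyphTemplate],
                   threshold: float = MATCH_THRESHOLD,
                   rotations=ROTATIONS, t: int = 0) -> list[Detection]:
    """Locate every template in one frame by rotation-max ZNCC.

    Each template gets the location maximising its correlation map;
    conflicts (two templates claiming centres closer than half a template
    width) are resolved greedily by descending score — the loser
    re-searches with a suppression zone masked out.  An absent glyph
    yields ``found=False`` (never an error: that is the signal the
    tracker imputes over).  Ties break lexicographically by mouse id.
    """
    frame = np.asarray(frame, dtype=float)
    tw = templates[0].image.shape[0]
    if frame.shape[0] < tw or frame.shape[1] < tw:
        raise ValueError("templates must be smaller than the frame")
    order = sorted(range(len(templates)), key=lambda i: templates[i].mouse_id)
    maps = {}
    for i in order:
        tm = templates[i]
        cm = None
        for k in rotations:
            m = match_template(frame, np.rot90(tm.image, k), pad_input=True)
            cm = m if cm is None else np.maximum(cm, m)
        maps[tm.mouse_id] = cm
    suppress_r = tw / 2.0
    pending = [templates[i].mouse_id for i in order]
    masks = {mid: np.ones(frame.shape, dtype=bool) for mid in pending}
    accepted: dict[str, tuple[int, int, float]] = {}
    rejected: set[str] = set()
    yy, xx = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
    while pending:
        best_mid, best_score, best_pos = None, -np.inf, None
        for mid in pending:
            cm = np.where(masks[mid], maps[mid], -np.inf)
            idx = np.unravel_index(np.argmax(cm), cm.shape)
            sc = cm[idx]
            if sc > best_score:  # strict: equal scores keep the earlier
                best_mid, best_score, best_pos = mid, sc, idx  # (lexicographic) id
        if not np.isfinite(best_score) or best_score < threshold:
            rejected.update(pending)
            break
        accepted[best_mid] = (best_pos[0], best_pos[1], float(best_score))
        pending.remove(best_mid)
        zone = (yy - best_pos[0]) ** 2 + (xx - best_pos[1]) ** 2 < suppress_r ** 2
        for mid in pending:
            masks[mid] &= ~zone
    out = []
    for tm in sorted(templates, key=lambda s: s.mouse_id):
        mid = tm.mouse_id
        if mid in accepted:
            r, c, sc = accepted[mid]
            out.append(Detection(t, mid, float(c), float(r), sc, True))
        else:
            out.append(Detection(t, mid, np.nan, np.nan, np.nan, False))
    return out


def track_stack(stack: FrameStack, templates: list[GlyphTemplate],
                threshold: float = MATCH_THRESHOLD,
                rotations=ROTATIONS) -> tuple[SessionRecording, list[Detection]]:
    """Identify every frame, convert to chamber mm and impute the gaps.

    Identification is per frame (memoryless), so an identity is
    re-acquired immediately after its glyph reappears.  Every template
    must be found in frame 0 (otherwise the head of its trajectory would
    be untrackable) — a ``ValueError`` is raised if not.

    Returns the imputed :class:`SessionRecording` together with the raw
    per-frame detections.
    """
    detections: list[Detection] = []
    for t in range(len(stack)):
        dets = identify_frame(stack.frames[t], templates, threshold,
                              rotations, t=t)
        if t == 0:
            missing = [d.mouse_id for d in dets if not d.found]
            if missing:
                raise ValueError(f"untrackable start: not found in frame 0: {missing}")
        detections.extend(dets)
    df = pd.DataFrame([vars(d) for d in detections])
    trajs = []
    for mid, sub in df.groupby("mouse_id", sort=True):
        sub = sub.sort_values("t", kind="stable")
        x_mm, y_mm = stack.chamber.px_to_mm(sub["x_px"].to_numpy(),
                                            sub["y_px"].to_numpy())
        trajs.append(Trajectory(str(mid), sub["t"].to_numpy(), x_mm, y_mm,
                                sub["found"].to_numpy(dtype=bool),
                                group=stack.groups.get(str(mid), "GH")))
    session = SessionRecording(stack.chamber, stack.schedule, stack.start, trajs)
    return session.impute(), detections


def detection_rate(detections: list[Detection], stack: FrameStack) -> dict[str, float]:
    """Fraction of (second, mouse) slots with a found identification.

    Counted over all ground-truth slots (visible or not), overall and per
    light/dark phase of the stack's schedule.
    """
    if stack.ground_truth is None:
        raise ValueError("detection rate needs ground truth")
    gt = stack.ground_truth[["t_s", "mouse_id"]].drop_duplicates()
    det = pd.DataFrame([(d.t, d.mouse_id, d.found) for d in detections],
                       columns=["t_s", "mouse_id", "found"])
    merged = gt.merge(det, on=["t_s", "mouse_id"], how="left")
    merged["found"] = merged["found"].astype("boolean").fillna(False).astype(bool)
    start_s = (stack.start.hour * 3600 + stack.start.minute * 60 + stack.start.second)
    light = stack.schedule.is_light(start_s + merged["t_s"].to_numpy())
    out = {"overall": float(merged["found"].mean())}
    for name, sel in (("light", light), ("dark", ~light)):
        out[name] = float(merged.loc[sel, "found"].mean()) if sel.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# disk I/O (PNG frame directory + ground_truth.csv; PNG templates)
# ---------------------------------------------------------------------------

def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)


def save_stack(stack: FrameStack, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in range(len(stack)):
        iio.imwrite(out / f"frame_{t:06d}.png", _to_u8(stack.frames[t]))
    if stack.ground_truth is not None:
        stack.ground_truth.to_csv(out / "ground_truth.csv", index=False)


def load_stack(frames_dir, chamber: ChamberSpec, schedule: LightSchedule,
               start, groups: dict[str, str] | None = None) -> FrameStack:
    d = Path(frames_dir)
    files = sorted(d.glob("frame_*.png"),
                   key=lambda p: int(re.findall(r"\d+", p.stem)[-1]))
    if not files:
        raise ValueError(f"no frame_*.png files in {frames_dir}")
    frames = np.stack([iio.imread(f).astype(float) / 255.0 for f in files])
    gt = None
    gt_path = d / "ground_truth.csv"
    if gt_path.exists():
        gt = pd.read_csv(gt_path, dtype={"mouse_id": str})
    return FrameStack(frames, chamber, schedule, start, ground_truth=gt,
                      groups=groups or {})


def save_templates(templates: list[GlyphTemplate], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tm in templates:
        iio.imwrite(out / f"{tm.mouse_id}.png", _to_u8(tm.image))


def load_templates(templates_dir) -> list[GlyphTemplate]:
    d = Path(templates_dir)
    files = sorted(d.glob("*.png"))
    if not files:
        raise ValueError(f"no template PNGs in {templates_dir}")
    return [GlyphTemplate(f.stem, iio.imread(f).astype(float) / 255.0)
            for f in files]
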