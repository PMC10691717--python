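"""Raw tracker output -> clean, kick-segmented, symmetrized data.

The tracker dialect is one row per (frame, fish) with pixel coordinates at
25 Hz.  The pipeline converts pixels to tank-centered mm (0.478 mm/pix),
repairs identity swaps by minimum-displacement assignment, removes episodes
where the whole group stalls (fastest fish below 40 mm/s for more than
2 s), and segments each trajectory into kicks from the smoothed speed
profile (Savitzky-Golay, degree 3, 0.36 s window; acceleration or
deceleration phases shorter than 0.08 s are merged; a kick starts where an
acceleration phase starts).

Headings are estimated from the velocity direction, since body orientation
is not part of the positional output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.signal import savgol_filter

from .core_model import Arena, wrap_angle

__all__ = [
    "MM_PER_PX",
    "ActiveSegment",
    "pixels_to_mm",
    "resolve_identities",
    "activity_filter",
    "detect_kicks",
    "mirror_augment",
    "build_kick_table",
]

MM_PER_PX = 0.478      # pixel-to-mm conversion of the recording setup
FRAME_DT = 0.04        # s, 25 Hz
SG_WINDOW_S = 0.36     # Savitzky-Golay window
SG_DEGREE = 3
MERGE_S = 0.08         # phases shorter than this are merged
SPEED_FLOOR = 40.0     # mm/s, activity threshold
STOP_S = 2.0           # s, tolerated lull before a stop is declared


@dataclass(frozen=True)
class ActiveSegment:
    """Contiguous frame window of sustained swimming activity
    (inclusive bounds)."""

    start_frame: int
    end_frame: int

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def pixels_to_mm(raw: pd.DataFrame, center_px: Tuple[float, float],
                 mm_per_px: float = MM_PER_PX) -> pd.DataFrame:
    """Convert tracker pixel coordinates to tank-centered metric ones:
    ``(x, y) = mm_per_px * (x_px - x0, y_px - y0)``."""
    out = raw.copy()
    out["x_mm"] = mm_per_px * (raw["x_px"] - center_px[0])
    out["y_mm"] = mm_per_px * (raw["y_px"] - center_px[1])
    if "time_s" not in out.columns:
        out["time_s"] = out["frame"] * FRAME_DT
    return out


# ---------------------------------------------------------------------------
# identity resolution
# ---------------------------------------------------------------------------

def resolve_identities(traj: pd.DataFrame) -> Tuple[pd.DataFrame, List[int]]:
    """Reassign fish labels so the total frame-to-frame displacement of the
    group is minimal (optimal assignment per consecutive frame pair).

    Frames whose detection count differs from the first frame's are dropped
    (and reported); the assignment chain restarts after a gap.  Returns the
    relabeled table and the list of dropped frames.
    """
    frames = np.sort(traj["frame"].unique())
    counts = traj.groupby("frame").size()
    n = int(counts.iloc[0])
    dropped = [int(f) for f in frames if counts.loc[f] != n]
    frames = np.array([f for f in frames if counts.loc[f] == n])

    cols = ["x_mm", "y_mm"] if "x_mm" in traj.columns else ["x_px", "y_px"]
    grouped = {f: g.reset_index(drop=True)
               for f, g in traj[traj["frame"].isin(frames)].groupby("frame")}

    out_rows = []
    prev_pos: Optional[np.ndarray] = None
    prev_frame: Optional[int] = None
    for f in frames:
        g = grouped[f]
        pos = g[cols].to_numpy(dtype=float)
        if prev_pos is None or (prev_frame is not None and f != prev_frame + 1):
            order = np.arange(n)          # chain (re)start: keep input order
        else:
            cost = np.linalg.norm(prev_pos[:, None, :] - pos[None, :, :],
                                  axis=2)
            _, order = linear_sum_assignment(cost)
        g = g.iloc[order].reset_index(drop=True)
        g = g.assign(fish_id=np.arange(n))
        out_rows.append(g)
        prev_pos = g[cols].to_numpy(dtype=float)
        prev_frame = int(f)
    out = pd.concat(out_rows, ignore_index=True)
    return out, dropped


# ---------------------------------------------------------------------------
# activity filter
# ---------------------------------------------------------------------------

def _speeds(traj: pd.DataFrame, dt: float = FRAME_DT) -> pd.DataFrame:
    """Per-(frame, fish) speed from centered finite differences."""
    parts = []
    for fid, g in traj.sort_values("frame").groupby("fish_id"):
        x = g["x_mm"].to_numpy()
        y = g["y_mm"].to_numpy()
        v = np.zeros(len(g))
        if len(g) > 1:
            v[1:-1] = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2]) / (2 * dt)
            v[0] = np.hypot(x[1] - x[0], y[1] - y[0]) / dt
            v[-1] = np.hypot(x[-1] - x[-2], y[-1] - y[-2]) / dt
        parts.append(pd.DataFrame({"frame": g["frame"].to_numpy(),
                                   "fish_id": fid, "speed": v}))
    return pd.concat(parts, ignore_index=True)


def activity_filter(traj: pd.DataFrame, speed_floor: float = SPEED_FLOOR,
                    stop_s: float = STOP_S,
                    dt: float = FRAME_DT) -> List[ActiveSegment]:
    """Windows of sustained activity.

    A stop is a run of frames in which the *fastest* fish stays below
    ``speed_floor`` for longer than ``stop_s``; stops are cut out and the
    remaining frames returned as segments.  Lulls shorter than ``stop_s``
    are kept.
    """
    sp = _speeds(traj, dt)
    vmax = sp.groupby("frame")["speed"].max()
    frames = vmax.index.to_numpy()
    slow = (vmax.to_numpy() < speed_floor)

    min_stop_frames = int(np.ceil(stop_s / dt))
    keep = np.ones(len(frames), dtype=bool)
    i = 0
    while i < len(frames):
        if slow[i]:
            j = i
            while j < len(frames) and slow[j]:
                j += 1
            if (j - i) > min_stop_frames:
                keep[i:j] = False
            i = j
        else:
            i += 1

    segments: List[ActiveSegment] = []
    i = 0
    while i < len(frames):
        if keep[i]:
            j = i
            while (j + 1 < len(frames) and keep[j + 1]
                   and frames[j + 1] == frames[j] + 1):
                j += 1
            segments.append(ActiveSegment(int(frames[i]), int(frames[j])))
            i = j + 1
        else:
            i += 1
    return segments


# ---------------------------------------------------------------------------
# kick segmentation
# ---------------------------------------------------------------------------

def _merge_short_runs(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Flip accel/decel runs shorter than ``min_len`` frames into their
    neighbors until none remain."""
    lab = labels.copy()
    while True:
        runs = []  # (start, stop_exclusive, value)
        s = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[s]:
                runs.append((s, i, lab[s]))
                s = i
        short = [r for r in runs[1:-1] if (r[1] - r[0]) < min_len]
        if not short:
            break
        s0, s1, val = min(short, key=lambda r: (r[1] - r[0], r[0]))
        lab[s0:s1] = -val
    return lab


def detect_kicks(traj: pd.DataFrame, dt: float = FRAME_DT,
                 sg_window_s: float = SG_WINDOW_S,
                 sg_degree: int = SG_DEGREE,
                 merge_s: float = MERGE_S,
                 refine_frames: int = 3,
                 min_rise: float = 5.0) -> pd.DataFrame:
    """Segment a single-fish trajectory into kicks.

    The smoothed speed profile (Savitzky-Golay) is split into alternating
    acceleration/deceleration phases, phases shorter than the merge window
    are absorbed, and a kick starts where an acceleration phase starts.
    Each detected onset is then refined to the local minimum of the
    backward-difference speed within ``refine_frames`` frames, which undoes
    the smoothing-induced shift of the minimum.

    Returns one row per kick: onset frame/time, duration ``tau_s`` (to the
    next onset), path length ``length_mm``, peak speed, and the glide
    heading (direction of the net onset-to-onset displacement; the glide is
    straight, so this is the post-decision heading).  ``dphi`` is the
    heading change decided at this onset, i.e. this kick's heading minus
    the previous kick's; it is NaN for the first kick.  The open-ended
    last acceleration is dropped.
    """
    g = traj.sort_values("frame").reset_index(drop=True)
    if g["fish_id"].nunique() > 1:
        raise ValueError("detect_kicks expects a single-fish trajectory")
    x = g["x_mm"].to_numpy()
    y = g["y_mm"].to_numpy()
    frames = g["frame"].to_numpy()
    times = g["time_s"].to_numpy() if "time_s" in g.columns else frames * dt

    window = int(round(sg_window_s / dt))
    if window % 2 == 0:
        window += 1
    if len(g) <= window:
        raise ValueError("segment shorter than the smoothing window")

    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    speed = np.hypot(vx, vy)
    smooth = savgol_filter(speed, window, sg_degree)

    ds = np.diff(smooth)
    labels = np.where(ds >= 0, 1, -1)          # accelerating / decelerating
    min_len = max(int(np.ceil(merge_s / dt)), 1)
    labels = _merge_short_runs(labels, min_len)

    # candidate onsets: first frame of each acceleration run (a run that
    # begins at the very start of the segment has an unseen true onset);
    # runs whose speed rise stays below min_rise (mm/s) are numerical
    # ripples of the smoother, not bursts
    candidates = []
    for i in range(1, len(labels)):
        if labels[i] == 1 and labels[i - 1] == -1:
            j = i
            while j < len(labels) and labels[j] == 1:
                j += 1
            if smooth[min(j, len(smooth) - 1)] - smooth[i] >= min_rise:
                candidates.append(i)

    # refine to the backward-difference speed minimum: the glide speed
    # decays until the onset frame and jumps right after it
    vb = np.full(len(x), np.inf)
    vb[1:] = np.hypot(np.diff(x), np.diff(y)) / dt
    onsets = []
    for i in candidates:
        lo = max(i - refine_frames, 1)
        hi = min(i + refine_frames + 1, len(x))
        j = int(lo + np.argmin(vb[lo:hi]))
        if not onsets or j > onsets[-1]:
            onsets.append(j)

    cols = ["fish_id", "onset_frame", "t_start", "tau_s", "length_mm",
            "v_peak", "heading_rad", "dphi"]
    if len(onsets) < 2:
        return pd.DataFrame(columns=cols)

    step = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(step)])

    rows = []
    fid = int(g["fish_id"].iloc[0])
    prev_heading = None
    for a, b in zip(onsets[:-1], onsets[1:]):
        heading = float(np.arctan2(y[b] - y[a], x[b] - x[a]))
        rows.append({
            "fish_id": fid,
            "onset_frame": int(frames[a]),
            "t_start": float(times[a]),
            "tau_s": float(times[b] - times[a]),
            "length_mm": float(cum[b] - cum[a]),
            "v_peak": float(smooth[a:b + 1].max()),
            "heading_rad": heading,
            "dphi": float(wrap_angle(heading - prev_heading))
            if prev_heading is not None else np.nan,
        })
        prev_heading = heading
    return pd.DataFrame(rows)


def build_kick_table(traj: pd.DataFrame, arena: Arena = Arena(),
                     dt: float = FRAME_DT) -> pd.DataFrame:
    """Kick table for a (possibly multi-fish) trajectory.

    Each kick row describes the heading decision at its onset: the wall
    state (``r_w``, ``theta_w``) and, for two-fish trajectories, the pair
    state (``d``, ``psi``, ``delta_phi``) of the partner at the onset
    frame.  Angles relative to the focal fish use its *incoming* heading
    (the previous kick's glide direction), since the decision is made
    before the turn; ``dphi`` is the turn itself.  Rows without a defined
    incoming heading (first kick of a fish) carry NaNs.
    """
    ids = np.sort(traj["fish_id"].unique())
    per_fish = {int(i): traj[traj["fish_id"] == i].sort_values("frame")
                .reset_index(drop=True) for i in ids}
    headings = {}
    for i, g in per_fish.items():
        vx = np.gradient(g["x_mm"].to_numpy(), dt)
        vy = np.gradient(g["y_mm"].to_numpy(), dt)
        headings[i] = np.arctan2(vy, vx)

    tables = []
    for i in ids:
        g = per_fish[int(i)]
        kicks = detect_kicks(g, dt=dt)
        if kicks.empty:
            continue
        frame_index = pd.Index(g["frame"])
        loc = frame_index.get_indexer(kicks["onset_frame"])
        xs = g["x_mm"].to_numpy()[loc]
        ys = g["y_mm"].to_numpy()[loc]
        incoming = np.concatenate([[np.nan],
                                   kicks["heading_rad"].to_numpy()[:-1]])
        kicks["r_w_mm"] = arena.R - np.hypot(xs, ys)
        kicks["theta_w_rad"] = wrap_angle(
            np.nan_to_num(incoming) - np.arctan2(ys, xs))
        kicks.loc[np.isnan(incoming), "theta_w_rad"] = np.nan
        if len(ids) == 2:
            j = int(ids[0] if i == ids[1] else ids[1])
            go = per_fish[j]
            oloc = pd.Index(go["frame"]).get_indexer(kicks["onset_frame"])
            ok = (oloc >= 0) & ~np.isnan(incoming)
            xo = go["x_mm"].to_numpy()[oloc]
            yo = go["y_mm"].to_numpy()[oloc]
            ho = headings[j][oloc]
            dx, dy = xo - xs, yo - ys
            kicks["d_mm"] = np.where(oloc >= 0, np.hypot(dx, dy), np.nan)
            kicks["psi_rad"] = np.where(
                ok, wrap_angle(np.arctan2(dy, dx) - np.nan_to_num(incoming)),
                np.nan)
            kicks["delta_phi_rad"] = np.where(
                ok, wrap_angle(ho - np.nan_to_num(incoming)), np.nan)
        tables.append(kicks)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# mirror symmetrization
# ---------------------------------------------------------------------------

_KICK_SIGN_FLIP = ["theta_w_rad", "psi_rad", "delta_phi_rad", "dphi",
                   "heading_rad"]


def mirror_augment(data: pd.DataFrame, kind: str = "auto") -> pd.DataFrame:
    """Append the left/right mirrored copy of a trajectory or kick table.

    Mirroring is the reflection ``y -> -y``, which negates headings and all
    signed angles.  The copy is flagged in a ``mirrored`` column.  The
    swimming statistics of the fish are left/right symmetric, so this
    doubles the data without biasing reconstructed interaction functions.
    """
    if kind == "auto":
        kind = "trajectory" if "x_mm" in data.columns and \
            "t_start" not in data.columns else "kicks"
    orig = data.copy()
    orig["mirrored"] = False
    def neg_wrap(values):
        out = np.asarray(values, dtype=float).copy()
        finite = np.isfinite(out)
        out[finite] = wrap_angle(-out[finite])
        return out

    mir = data.copy()
    if kind == "trajectory":
        mir["y_mm"] = -mir["y_mm"]
        if "heading_rad" in mir.columns:
            mir["heading_rad"] = neg_wrap(mir["heading_rad"].to_numpy())
    elif kind == "kicks":
        for col in _KICK_SIGN_FLIP:
            if col in mir.columns:
                mir[col] = neg_wrap(mir[col].to_numpy())
    else:
        raise ValueError(f"unknown kind {kind!r}")
    mir["mirrored"] = True
    return pd.concat([orig, mir], ignore_index=True)
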