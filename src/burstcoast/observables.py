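"""Collective and pairwise descriptors of fish trajectories.

Per-frame group observables: dispersion (radius of gyration) ``D``,
polarization ``P``, milling ``M``, per-fish distance/orientation to the
wall, and nearest-neighbor distances.  The milling index is computed in the
barycenter frame: it is the absolute mean of ``sin(phibar - thetabar)``,
where ``phibar`` is the direction of a fish's velocity relative to the
barycenter and ``thetabar`` its position angle relative to the barycenter.

Trajectory-level helpers estimate velocities by centered finite differences
on the 0.04 s sampling grid (one-sided at the endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_model import Arena, PairState, WallState, wrap_angle

__all__ = [
    "GroupObservables",
    "dispersion",
    "polarization",
    "milling",
    "wall_state",
    "pair_state",
    "nearest_neighbor_distances",
    "leader_follower",
    "evaluate_trajectory",
    "summarize",
]


@dataclass
class GroupObservables:
    """Per-frame time series of the group descriptors plus per-fish wall
    state and NND; produced by :func:`evaluate_trajectory`."""

    frame_table: pd.DataFrame     # time_s, D_mm, P, M, barycenter fields
    fish_table: pd.DataFrame      # time_s, fish_id, r_w_mm, theta_w_rad, nnd_mm


def dispersion(positions: np.ndarray) -> float:
    """Radius of gyration: rms distance of the fish to their barycenter."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    bary = pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pos - bary) ** 2, axis=1))))


def polarization(headings: np.ndarray) -> float:
    """Norm of the mean heading unit vector, in [0, 1]."""
    h = np.atleast_1d(np.asarray(headings, dtype=float))
    return float(np.hypot(np.cos(h).mean(), np.sin(h).mean()))


def milling(positions: np.ndarray, headings: np.ndarray,
            speeds: Optional[np.ndarray] = None) -> float:
    """Milling index: ``|mean(sin(phibar - thetabar))|`` in the barycenter
    frame, in [0, 1] and independent of the rotation direction.

    Velocities are ``speed * (cos h, sin h)``; with ``speeds=None`` unit
    speeds are assumed.  The barycenter velocity is subtracted before
    taking the relative velocity direction.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    h = np.atleast_1d(np.asarray(headings, dtype=float))
    v = np.stack([np.cos(h), np.sin(h)], axis=1)
    if speeds is not None:
        v = v * np.asarray(speeds, dtype=float)[:, None]
    rel_p = pos - pos.mean(axis=0)
    rel_v = v - v.mean(axis=0)
    theta_bar = np.arctan2(rel_p[:, 1], rel_p[:, 0])
    phi_bar = np.arctan2(rel_v[:, 1], rel_v[:, 0])
    return float(abs(np.mean(np.sin(phi_bar - theta_bar))))


def wall_state(position: np.ndarray, heading: float, arena: Arena) -> WallState:
    """Distance and relative orientation of a fish to the circular wall."""
    x, y = float(position[0]), float(position[1])
    r = np.hypot(x, y)
    if r > arena.R + 1e-9:
        raise ValueError("fish outside the arena")
    theta_w = wrap_angle(heading - np.arctan2(y, x)) if r > 1e-12 else 0.0
    return WallState(r_w=float(arena.R - r), theta_w=float(theta_w))


def pair_state(pos_i: np.ndarray, heading_i: float,
               pos_j: np.ndarray, heading_j: float) -> PairState:
    """Relative state (d, psi, delta_phi) of fish j seen from fish i."""
    dx = float(pos_j[0] - pos_i[0])
    dy = float(pos_j[1] - pos_i[1])
    d = float(np.hypot(dx, dy))
    psi = wrap_angle(np.arctan2(dy, dx) - heading_i)
    dphi = wrap_angle(heading_j - heading_i)
    return PairState(d=d, psi=float(psi), delta_phi=float(dphi))


def nearest_neighbor_distances(positions: np.ndarray) -> np.ndarray:
    """Per-fish distance to the nearest other fish."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = pos.shape[0]
    if n < 2:
        return np.full(n, np.nan)
    dm = squareform(pdist(pos))
    np.fill_diagonal(dm, np.inf)
    return dm.min(axis=1)


def leader_follower(pos_a, heading_a, pos_b, heading_b,
                    ids: Tuple[int, int] = (0, 1),
                    tol: float = 1e-9):
    """Geometrical leader/follower of a pair.

    The leader is the fish with the larger absolute viewing angle of the
    other (it would have to turn the most to face its partner).  Returns
    ``(leader_id, follower_id, tied)``; an exact tie goes to the lower id
    and is flagged.
    """
    psi_a = abs(pair_state(pos_a, heading_a, pos_b, heading_b).psi)
    psi_b = abs(pair_state(pos_b, heading_b, pos_a, heading_a).psi)
    if abs(psi_a - psi_b) <= tol:
        lo, hi = sorted(ids)
        return lo, hi, True
    if psi_a > psi_b:
        return ids[0], ids[1], False
    return ids[1], ids[0], False


# ---------------------------------------------------------------------------
# trajectory pipeline
# ---------------------------------------------------------------------------

def _pivot(traj: pd.DataFrame):
    x = traj.pivot(index="frame", columns="fish_id", values="x_mm")
    y = traj.pivot(index="frame", columns="fish_id", values="y_mm")
    t = traj.groupby("frame")["time_s"].first()
    return x.to_numpy(), y.to_numpy(), t.to_numpy(), x.index.to_numpy(), \
        x.columns.to_numpy()


def _finite_diff(a: np.ndarray, dt: float) -> np.ndarray:
    """Centered differences along axis 0, one-sided at the endpoints."""
    v = np.empty_like(a)
    if a.shape[0] == 1:
        v[:] = 0.0
        return v
    v[1:-1] = (a[2:] - a[:-2]) / (2.0 * dt)
    v[0] = (a[1] - a[0]) / dt
    v[-1] = (a[-1] - a[-2]) / dt
    return v


def evaluate_trajectory(traj: pd.DataFrame, arena: Arena = Arena(),
                        heading_from: str = "auto") -> GroupObservables:
    """Compute per-frame group and per-fish observables from a trajectory
    table with columns frame, time_s, fish_id, x_mm, y_mm [, heading_rad].

    ``heading_from``: "column" uses the stored heading, "velocity" the
    finite-difference velocity direction, "auto" prefers the column.
    """
    X, Y, times, frames, ids = _pivot(traj)
    n_frames, n = X.shape
    dt = float(np.median(np.diff(times))) if n_frames > 1 else 1.0
    vx = _finite_diff(X, dt)
    vy = _finite_diff(Y, dt)
    if heading_from == "column" or (heading_from == "auto"
                                    and "heading_rad" in traj.columns):
        H = traj.pivot(index="frame", columns="fish_id",
                       values="heading_rad").to_numpy()
    else:
        H = np.arctan2(vy, vx)

    bx, by = X.mean(axis=1), Y.mean(axis=1)
    bvx, bvy = vx.mean(axis=1), vy.mean(axis=1)

    # dispersion
    D = np.sqrt(((X - bx[:, None]) ** 2 + (Y - by[:, None]) ** 2).mean(axis=1))
    # polarization
    P = np.hypot(np.cos(H).mean(axis=1), np.sin(H).mean(axis=1))
    # milling in the barycenter frame, from actual relative velocities
    rx, ry = X - bx[:, None], Y - by[:, None]
    rvx, rvy = vx - bvx[:, None], vy - bvy[:, None]
    theta_bar = np.arctan2(ry, rx)
    phi_bar = np.arctan2(rvy, rvx)
    M = np.abs(np.sin(phi_bar - theta_bar).mean(axis=1))

    r = np.hypot(X, Y)
    r_w = arena.R - r
    theta_pos = np.arctan2(Y, X)
    theta_w = wrap_angle(H - theta_pos)

    if n >= 2:
        nnd = np.empty_like(X)
        for f in range(n_frames):
            nnd[f] = nearest_neighbor_distances(
                np.stack([X[f], Y[f]], axis=1))
    else:
        nnd = np.full_like(X, np.nan)

    frame_table = pd.DataFrame({
        "frame": frames, "time_s": times,
        "D_mm": D, "P": P, "M": M,
        "bary_x_mm": bx, "bary_y_mm": by,
        "bary_vx": bvx, "bary_vy": bvy,
        "bary_heading_rad": np.arctan2(bvy, bvx),
        "bary_r_w_mm": arena.R - np.hypot(bx, by),
        "bary_theta_w_rad": wrap_angle(np.arctan2(bvy, bvx)
                                       - np.arctan2(by, bx)),
    })
    fish_table = pd.DataFrame({
        "frame": np.repeat(frames, n),
        "time_s": np.repeat(times, n),
        "fish_id": np.tile(ids, n_frames),
        "r_w_mm": r_w.ravel(),
        "theta_w_rad": theta_w.ravel(),
        "nnd_mm": nnd.ravel(),
    })
    return GroupObservables(frame_table=frame_table, fish_table=fish_table)


def summarize(obs: GroupObservables) -> dict:
    """Time-averaged scalars: <r_w>, <NND>, <D>, <P>, <M> (mm / unitless)."""
    ft, gt = obs.fish_table, obs.frame_table
    return {
        "r_w_mm": float(ft["r_w_mm"].mean()),
        "nnd_mm": float(ft["nnd_mm"].mean()) if ft["nnd_mm"].notna().any()
        else float("nan"),
        "D_mm": float(gt["D_mm"].mean()),
        "P": float(gt["P"].mean()),
        "M": float(gt["M"].mean()),
    }
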