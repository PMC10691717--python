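"""Asynchronous kick-event simulation of N fish in a circular arena.

Each fish moves in discrete kicks: at the kick instant it chooses a new
heading (spontaneous noise + wall repulsion + social terms from its k most
influential neighbors), then glides along a straight segment whose length,
duration, and quasi-exponential speed decay come from per-light-condition
samplers.  Kicks of different fish are asynchronous; the engine processes
fish in order of next kick time.

A candidate kick is rejected unless the fish would stay a comfort distance
``l_c`` inside the wall:  ``|u + (l + l_c) e(phi + dphi)| < R``.  On
rejection the spontaneous angle, the kick length, and the kick duration are
resampled jointly (wall and social contributions kept fixed); after 1000
failed tries the spontaneous angle falls back to a uniform draw in
``(-pi, pi)`` until the constraint holds.

Kick-length sampling depends on group size:

* N = 1  -- peak speed and duration are sampled, the length follows from
  ``l = v tau0 (1 - exp(-tau/tau0))``;
* N = 2  -- the length is drawn with mean given by the distance-dependent
  modulation ``F_m(d)`` of the most influential neighbor;
* N >= 3 -- the length is drawn with a fixed per-condition mean ``l_bar``
  (the pair modulation is neglected in larger groups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core_model import (
    Arena,
    LightParams,
    PairState,
    _social_arrays,
    noise_sd,
    wall_angular,
    wall_force,
    wrap_angle,
)

__all__ = [
    "KickEvent",
    "FishState",
    "SimulationRun",
    "SimulationResult",
    "glide_position",
    "glide_displacement",
    "kick_length_from_speed",
    "sample_kick_duration",
    "sample_peak_speed",
    "modulated_mean_length",
    "sample_kick_length",
    "influence",
    "select_neighbors",
    "attempt_heading",
    "run_simulation",
]

MAX_REJECT = 1000
DT_OUT = 0.04  # output sampling step, s (25 Hz, the tracker frame rate)


@dataclass(frozen=True)
class KickEvent:
    """One burst-and-coast decision."""

    fish_id: int
    t_start: float            # s
    tau: float                # duration, s
    length: float             # mm
    v_peak: float             # mm/s
    origin: Tuple[float, float]   # (x, y) at kick onset, mm
    heading_new: float        # heading during the glide, rad
    dphi_random: float        # spontaneous component of the turn, rad
    dphi_wall: float          # wall component, rad
    dphi_social: float        # social component, rad


@dataclass
class FishState:
    """Current kick of one fish; positions at intermediate times follow by
    glide interpolation."""

    kick: KickEvent
    tau0: float

    def position(self, t: float) -> Tuple[float, float]:
        dt = t - self.kick.t_start
        dt = min(max(dt, 0.0), self.kick.tau)  # clamp at kick end
        return glide_position(self.kick, dt, self.tau0)

    @property
    def heading(self) -> float:
        return self.kick.heading_new


@dataclass
class SimulationRun:
    """Configuration of one simulation run."""

    n_fish: int
    duration: float           # s
    seed: int
    params: LightParams
    arena: Arena = field(default_factory=Arena)
    dt_out: float = DT_OUT
    record_kicks: bool = True

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ValueError("need at least one fish")
        if not (self.duration > 0):
            raise ValueError("duration must be positive")
        if not (self.dt_out > 0):
            raise ValueError("output step must be positive")


@dataclass
class SimulationResult:
    trajectory: pd.DataFrame  # frame, time_s, fish_id, x_mm, y_mm, heading_rad
    kicks: pd.DataFrame       # KickEvent fields, one row per kick
    config: SimulationRun


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def glide_displacement(length: float, tau: float, dt, tau0: float):
    """Distance covered ``dt`` seconds into a kick of given length/duration:
    ``l (1 - exp(-dt/tau0)) / (1 - exp(-tau/tau0))``."""
    dt = np.asarray(dt, dtype=float)
    out = length * (-np.expm1(-dt / tau0)) / (-math.expm1(-tau / tau0))
    return float(out) if out.ndim == 0 else out


def glide_position(k: KickEvent, dt: float, tau0: float) -> Tuple[float, float]:
    """Position ``dt`` seconds after kick onset (0 <= dt <= tau)."""
    if dt < 0 or dt > k.tau:
        raise ValueError(f"dt={dt} outside kick of duration {k.tau}")
    s = glide_displacement(k.length, k.tau, dt, tau0)
    return (k.origin[0] + s * math.cos(k.heading_new),
            k.origin[1] + s * math.sin(k.heading_new))


def kick_length_from_speed(v_peak: float, tau: float, tau0: float) -> float:
    """Kick length implied by peak speed and duration:
    ``l = v tau0 (1 - exp(-tau/tau0))``."""
    return v_peak * tau0 * (-math.expm1(-tau / tau0))


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _sample_two_exponential(mean: float, floor: float,
                            rng: np.random.Generator) -> float:
    """Draw ``-0.5 * mean * ln(r1 r2)`` (Gamma, shape 2, mean ``mean``),
    resampling while the draw falls below ``floor``."""
    while True:
        r1, r2 = rng.random(), rng.random()
        x = -0.5 * mean * math.log(r1 * r2)
        if x >= floor:
            return x


def sample_kick_duration(p: LightParams, rng: np.random.Generator) -> float:
    """Kick duration ``tau = -0.5 tau_bar ln(r1 r2)``, rejecting draws
    below ``tau_min``."""
    return _sample_two_exponential(p.tau_bar, p.tau_min, rng)


def sample_peak_speed(p: LightParams, rng: np.random.Generator) -> float:
    """Peak speed from the same two-exponential family as the duration,
    with mean ``v_bar`` and optional lower truncation ``v_min``."""
    return _sample_two_exponential(p.v_bar, p.v_min, rng)


def modulated_mean_length(d, p: LightParams):
    """Mean kick length as a function of the distance to the most
    influential neighbor: ``F_m(d) = l_m - gamma_m (d + d_m) exp(-d/l_m)``.

    Saturates at ``l_m`` for large ``d``; shortest kicks near contact
    (stationary point at ``d = l_m - d_m``).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = p.l_m - p.gamma_m * (d + p.d_m) * np.exp(-d / p.l_m)
    return float(out) if out.ndim == 0 else out


def sample_kick_length(p: LightParams, n_fish: int,
                       d_influential: Optional[float],
                       rng: np.random.Generator,
                       tau: Optional[float] = None) -> Tuple[float, float]:
    """Sample a kick length; returns ``(length, v_peak)``.

    * ``n_fish == 1``: peak speed is sampled and the length follows from
      the glide relation (``tau`` required).
    * ``n_fish == 2``: two-exponential draw with mean ``F_m(d)`` of the
      most influential neighbor (``d_influential`` required).
    * ``n_fish >= 3``: two-exponential draw with fixed mean ``l_bar``.

    For the group modes the recorded peak speed is the one implied by the
    glide relation when ``tau`` is given.
    """
    if n_fish == 1:
        if tau is None:
            raise ValueError("single-fish mode needs the kick duration")
        v = sample_peak_speed(p, rng)
        return kick_length_from_speed(v, tau, p.tau0), v
    if n_fish == 2:
        if d_influential is None:
            raise ValueError("pair mode needs the neighbor distance")
        mean = max(modulated_mean_length(d_influential, p), 1e-6)
    else:
        mean = p.l_bar
    length = _sample_two_exponential(mean, 0.0, rng)
    v = length / (p.tau0 * (-math.expm1(-tau / p.tau0))) if tau else float("nan")
    return length, v


# ---------------------------------------------------------------------------
# social machinery
# ---------------------------------------------------------------------------

def influence(s: PairState, p: LightParams) -> float:
    """Influence of a neighbor: absolute social contribution ``|dphi_S|``."""
    return abs(float(_social_arrays(s.d, s.psi, s.delta_phi, p)))


def _pair_arrays(x: float, y: float, phi: float,
                 ox: np.ndarray, oy: np.ndarray, ophi: np.ndarray):
    """Vectorized (d, psi, delta_phi) of many neighbors seen from a focal
    fish at (x, y) with heading phi."""
    dx, dy = ox - x, oy - y
    d = np.hypot(dx, dy)
    psi = wrap_angle(np.arctan2(dy, dx) - phi)
    dphi = wrap_angle(ophi - phi)
    return d, psi, dphi


def select_neighbors(focal_idx: int, xs: np.ndarray, ys: np.ndarray,
                     phis: np.ndarray, p: LightParams,
                     k: Optional[int] = None) -> np.ndarray:
    """Indices of the ``k`` most influential neighbors of ``focal_idx``.

    Influences are evaluated at the interpolated states passed in; ties are
    broken by smaller fish index.  Returns fewer indices when there are
    fewer than ``k`` neighbors.
    """
    k = p.k if k is None else k
    n = len(xs)
    others = np.array([j for j in range(n) if j != focal_idx])
    if others.size == 0:
        return others
    d, psi, dphi = _pair_arrays(xs[focal_idx], ys[focal_idx], phis[focal_idx],
                                xs[others], ys[others], phis[others])
    infl = np.abs(_social_arrays(d, psi, dphi, p))
    # stable sort on (-influence, id): ties go to the smaller fish id
    order = np.lexsort((others, -infl))
    return others[order[:min(k, others.size)]]


def attempt_heading(x: float, y: float, phi: float, dphi: float,
                    length: float, arena: Arena, l_c: float) -> bool:
    """Comfort-distance acceptance rule: the point ``(l + l_c)`` ahead of
    the candidate heading must lie strictly inside the arena."""
    h = phi + dphi
    ex = x + (length + l_c) * math.cos(h)
    ey = y + (length + l_c) * math.sin(h)
    return math.hypot(ex, ey) < arena.R


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class _Engine:
    """Struct-of-arrays event loop; one instance per run."""

    def __init__(self, cfg: SimulationRun):
        self.cfg = cfg
        self.p = cfg.params
        self.arena = cfg.arena
        self.rng = np.random.default_rng(cfg.seed)
        n = cfg.n_fish
        # per-fish current kick
        self.ox = np.zeros(n)
        self.oy = np.zeros(n)
        self.heading = np.zeros(n)
        self.length = np.zeros(n)
        self.tau = np.full(n, 1e-9)
        self.t0 = np.zeros(n)
        self.kick_rows: List[tuple] = []
        self.kicks_per_fish: List[List[tuple]] = [[] for _ in range(n)]

    # -- initial conditions: uniform in the disk of radius R - 2 l_c,
    # uniform headings, first kicks sampled fresh at t = 0 in id order.
    def init_state(self) -> None:
        n = self.cfg.n_fish
        rmax = max(self.arena.R - 2.0 * self.p.l_c, 0.1 * self.arena.R)
        r = rmax * np.sqrt(self.rng.random(n))
        th = self.rng.uniform(-math.pi, math.pi, n)
        self.ox[:] = r * np.cos(th)
        self.oy[:] = r * np.sin(th)
        self.heading[:] = self.rng.uniform(-math.pi, math.pi, n)
        for i in range(n):
            self._kick(i, 0.0)

    def _interp_all(self, t: float):
        """Positions of all fish at time t via glide interpolation
        (clamped at kick end)."""
        dt = np.clip(t - self.t0, 0.0, self.tau)
        s = self.length * (-np.expm1(-dt / self.p.tau0)) / \
            (-np.expm1(-self.tau / self.p.tau0))
        return (self.ox + s * np.cos(self.heading),
                self.oy + s * np.sin(self.heading))

    def _kick(self, i: int, t: float) -> None:
        p, rng, arena = self.p, self.rng, self.arena
        n = self.cfg.n_fish
        # position at the end of the previous kick
        if t > self.t0[i]:
            x, y = FishState(self._current_event(i), p.tau0).position(t)
        else:
            x, y = self.ox[i], self.oy[i]
        phi = self.heading[i]
        r = math.hypot(x, y)
        r_w = max(arena.R - r, 0.0)
        theta_w = wrap_angle(phi - math.atan2(y, x)) if r > 1e-12 else 0.0
        dphi_w = wall_force(r_w, p) * wall_angular(theta_w)

        dphi_s = 0.0
        d_inf: Optional[float] = None
        if n > 1:
            xs, ys = self._interp_all(t)
            xs[i], ys[i] = x, y
            nb = select_neighbors(i, xs, ys, self.heading, p)
            if nb.size:
                d, psi, dph = _pair_arrays(x, y, phi, xs[nb], ys[nb],
                                           self.heading[nb])
                contrib = _social_arrays(d, psi, dph, p)
                dphi_s = float(np.sum(contrib))
                d_inf = float(d[0])  # most influential neighbor

        sd = noise_sd(r_w, p)
        dphi_r = tau = length = v_peak = 0.0
        accepted = False
        for _ in range(MAX_REJECT):
            dphi_r = sd * rng.standard_normal()
            tau = sample_kick_duration(p, rng)
            length, v_peak = sample_kick_length(p, n, d_inf, rng, tau=tau)
            if attempt_heading(x, y, phi, dphi_r + dphi_w + dphi_s,
                               length, arena, p.l_c):
                accepted = True
                break
        if not accepted:
            # uniform-heading fallback guarantees progress
            while True:
                dphi_r = rng.uniform(-math.pi, math.pi)
                if attempt_heading(x, y, phi, dphi_r + dphi_w + dphi_s,
                                   length, arena, p.l_c):
                    break

        new_heading = wrap_angle(phi + dphi_r + dphi_w + dphi_s)
        self.ox[i], self.oy[i] = x, y
        self.heading[i] = new_heading
        self.length[i] = length
        self.tau[i] = tau
        self.t0[i] = t
        row = (i, t, tau, length, v_peak, x, y, new_heading,
               dphi_r, dphi_w, dphi_s)
        self.kicks_per_fish[i].append(row)
        if self.cfg.record_kicks:
            self.kick_rows.append(row)

    def _current_event(self, i: int) -> KickEvent:
        return KickEvent(i, self.t0[i], self.tau[i], self.length[i],
                         float("nan"), (self.ox[i], self.oy[i]),
                         self.heading[i], 0.0, 0.0, 0.0)

    def run(self) -> None:
        self.init_state()
        duration = self.cfg.duration
        t_next = self.t0 + self.tau
        while True:
            i = int(np.argmin(t_next))  # first occurrence = smallest id
            t = float(t_next[i])
            if t >= duration:
                break
            self._kick(i, t)
            t_next[i] = t + self.tau[i]

    def trajectory(self) -> pd.DataFrame:
        p, cfg = self.p, self.cfg
        n_frames = int(math.floor(cfg.duration / cfg.dt_out)) + 1
        times = np.arange(n_frames) * cfg.dt_out
        frames_out = []
        for i in range(cfg.n_fish):
            rows = self.kicks_per_fish[i]
            t0 = np.array([r[1] for r in rows])
            tau = np.array([r[2] for r in rows])
            ln = np.array([r[3] for r in rows])
            ox = np.array([r[5] for r in rows])
            oy = np.array([r[6] for r in rows])
            hd = np.array([r[7] for r in rows])
            idx = np.searchsorted(t0, times, side="right") - 1
            dt = np.clip(times - t0[idx], 0.0, tau[idx])
            s = ln[idx] * (-np.expm1(-dt / p.tau0)) / \
                (-np.expm1(-tau[idx] / p.tau0))
            frames_out.append(pd.DataFrame({
                "frame": np.arange(n_frames),
                "time_s": times,
                "fish_id": i,
                "x_mm": ox[idx] + s * np.cos(hd[idx]),
                "y_mm": oy[idx] + s * np.sin(hd[idx]),
                "heading_rad": hd[idx],
            }))
        out = pd.concat(frames_out, ignore_index=True)
        return out.sort_values(["frame", "fish_id"], ignore_index=True)

    def kick_frame(self) -> pd.DataFrame:
        cols = ["fish_id", "t_start", "tau_s", "length_mm", "v_peak",
                "x0_mm", "y0_mm", "heading_rad", "dphi_random", "dphi_wall",
                "dphi_social"]
        df = pd.DataFrame(self.kick_rows, columns=cols)
        if df.empty:
            return df
        # decision-time state: total turn and the wall state seen with the
        # incoming (pre-turn) heading, ready for reconstruction
        df["dphi"] = df["dphi_random"] + df["dphi_wall"] + df["dphi_social"]
        incoming = df["heading_rad"] - df["dphi"]
        df["r_w_mm"] = self.arena.R - np.hypot(df["x0_mm"], df["y0_mm"])
        df["theta_w_rad"] = wrap_angle(
            incoming.to_numpy() - np.arctan2(df["y0_mm"], df["x0_mm"]))
        return df


def run_simulation(cfg: SimulationRun) -> SimulationResult:
    """Run one seeded simulation; deterministic given (seed, params)."""
    eng = _Engine(cfg)
    eng.run()
    return SimulationResult(eng.trajectory(), eng.kick_frame(), cfg)
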