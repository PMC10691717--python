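"""Synthetic-data generation: every pipeline stage is testable offline.

Three generators cover the three kinds of input the package consumes:

* :func:`make_simulated_cohort` -- a full simulation run (trajectory plus
  ground-truth kick log);
* :func:`make_tracker_file` -- a tracker-dialect pixel CSV derived from a
  simulation, optionally corrupted with label swaps, dropped frames, stop
  episodes and pixel quantization;
* :func:`make_kick_table` -- kick tables drawn directly from the model
  equations at prescribed state distributions, bypassing the simulator,
  for fast reconstruction tests with known ground truth.

Every fixture is generated from a seed and is bit-identical on
regeneration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core_model import (
    Arena,
    LightParams,
    _social_arrays,
    noise_sd,
    wall_angular,
    wall_force,
)
from .preprocess import FRAME_DT, MM_PER_PX
from .simulator import (
    SimulationResult,
    SimulationRun,
    modulated_mean_length,
    run_simulation,
)

__all__ = [
    "FixtureSpec",
    "make_simulated_cohort",
    "make_tracker_file",
    "make_kick_table",
]

SCENARIO_N = {"single": 1, "pair": 2, "group5": 5, "group25": 25,
              "tracker": 5}


@dataclass(frozen=True)
class FixtureSpec:
    """Serializable description of a synthetic scenario."""

    scenario: str
    params: LightParams
    seed: int = 0
    duration: float = 120.0          # s
    n_fish: Optional[int] = None     # defaults from the scenario name
    arena: Arena = field(default_factory=Arena)
    # corruption options (tracker fixtures)
    n_label_swaps: int = 0
    n_dropped_frames: int = 0
    stop_episodes: int = 0
    stop_duration: float = 3.0       # s
    quantize_pixels: bool = True

    @property
    def group_size(self) -> int:
        if self.n_fish is not None:
            return self.n_fish
        try:
            return SCENARIO_N[self.scenario]
        except KeyError:
            raise ValueError(f"unknown scenario {self.scenario!r}") from None


def make_simulated_cohort(spec: FixtureSpec) -> SimulationResult:
    """Run the simulator for a scenario; returns trajectory + kick log."""
    cfg = SimulationRun(n_fish=spec.group_size, duration=spec.duration,
                        seed=spec.seed, params=spec.params, arena=spec.arena)
    return run_simulation(cfg)


def make_tracker_file(spec: FixtureSpec,
                      center_px: Tuple[float, float] = (540.0, 540.0),
                      mm_per_px: float = MM_PER_PX) -> pd.DataFrame:
    """Tracker-dialect table (frame, id, x_px, y_px) from a simulation.

    Inverts the metric conversion, optionally quantizing to whole pixels,
    and injects the requested corruptions: random per-frame label
    permutations, dropped frames, and stop episodes during which all fish
    freeze in place.
    """
    result = make_simulated_cohort(spec)
    traj = result.trajectory.copy()
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.group_size
    frames = np.sort(traj["frame"].unique())

    if spec.stop_episodes > 0:
        stop_frames = int(round(spec.stop_duration / FRAME_DT))
        starts = rng.choice(
            frames[frames < frames.max() - stop_frames],
            size=spec.stop_episodes, replace=False)
        X = traj.pivot(index="frame", columns="fish_id", values="x_mm")
        Y = traj.pivot(index="frame", columns="fish_id", values="y_mm")
        for s in np.sort(starts):
            sl = slice(int(s), int(s) + stop_frames)
            X.iloc[sl] = X.iloc[int(s)].to_numpy()
            Y.iloc[sl] = Y.iloc[int(s)].to_numpy()
        traj = traj.set_index(["frame", "fish_id"])
        traj["x_mm"] = X.stack()
        traj["y_mm"] = Y.stack()
        traj = traj.reset_index()

    x_px = traj["x_mm"].to_numpy() / mm_per_px + center_px[0]
    y_px = traj["y_mm"].to_numpy() / mm_per_px + center_px[1]
    if spec.quantize_pixels:
        x_px, y_px = np.round(x_px), np.round(y_px)
    out = pd.DataFrame({"frame": traj["frame"], "id": traj["fish_id"],
                        "x_px": x_px, "y_px": y_px})

    if spec.n_label_swaps > 0 and n > 1:
        swap_frames = rng.choice(frames[1:], size=spec.n_label_swaps,
                                 replace=False)
        for f in swap_frames:
            perm = rng.permutation(n)
            mask = out["frame"] == f
            ids = out.loc[mask, "id"].to_numpy()
            out.loc[mask, "id"] = perm[ids]
    if spec.n_dropped_frames > 0:
        dropped = rng.choice(frames[1:-1], size=spec.n_dropped_frames,
                             replace=False)
        out = out[~out["frame"].isin(dropped)]
    return out.sort_values(["frame", "id"], ignore_index=True)


def make_kick_table(params: LightParams, n_kicks: int, mode: str,
                    seed: int = 0, arena: Arena = Arena(),
                    d_max: float = 150.0,
                    r_w_fixed: float = 150.0) -> pd.DataFrame:
    """Kick table drawn directly from the model at prescribed states.

    * ``mode="wall"``: single-fish kicks with ``r_w`` uniform in
      (0, min(120, R)) and ``theta_w`` uniform; ``dphi`` is wall term plus
      wall-reduced Gaussian noise.
    * ``mode="social"``: pair kicks with ``d`` uniform in (0, d_max) and
      both angles uniform, far from the wall (``r_w = r_w_fixed``);
      ``dphi`` is the social term plus Gaussian noise.
    * ``mode="modulation"``: pair kicks whose lengths are drawn from the
      two-exponential distribution with mean ``F_m(d)``.

    The injected parameters are the ground truth for recovery tests.
    """
    rng = np.random.default_rng(seed)
    p = params
    if mode == "wall":
        r_w = rng.uniform(0.0, min(120.0, arena.R), n_kicks)
        theta_w = rng.uniform(-math.pi, math.pi, n_kicks)
        dphi = (noise_sd(r_w, p) * rng.standard_normal(n_kicks)
                + wall_force(r_w, p) * wall_angular(theta_w))
        return pd.DataFrame({"fish_id": 0, "r_w_mm": r_w,
                             "theta_w_rad": theta_w, "dphi": dphi})
    if mode == "social":
        d = rng.uniform(0.0, d_max, n_kicks)
        psi = rng.uniform(-math.pi, math.pi, n_kicks)
        dph = rng.uniform(-math.pi, math.pi, n_kicks)
        r_w = np.full(n_kicks, r_w_fixed)
        dphi = (noise_sd(r_w, p) * rng.standard_normal(n_kicks)
                + _social_arrays(d, psi, dph, p))
        return pd.DataFrame({"fish_id": 0, "r_w_mm": r_w, "d_mm": d,
                             "psi_rad": psi, "delta_phi_rad": dph,
                             "dphi": dphi})
    if mode == "modulation":
        d = rng.uniform(0.0, d_max, n_kicks)
        mean = np.maximum(modulated_mean_length(d, p), 1e-6)
        lengths = -0.5 * mean * np.log(rng.random(n_kicks)
                                       * rng.random(n_kicks))
        return pd.DataFrame({"fish_id": 0, "d_mm": d,
                             "length_mm": lengths})
    raise ValueError(f"unknown mode {mode!r}")
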