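"""File dialects and parameter-file handling.

All tables are comma-separated UTF-8 with a header row; units are encoded
in the column names (``_mm``, ``_s``, ``_rad``).  Angles are stored in
radians.  Parameter files are flat YAML key-value maps whose keys are the
``LightParams`` field names (see ``params/schema.md`` for units); packaged
defaults exist for the five light conditions (0.5, 1, 1.5, 5, 50 lx) and
group sizes 1, 2, 5 and 25.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd
import yaml

from .core_model import Arena, LightParams
from .observables import evaluate_trajectory
from .reconstruction import FitResult

__all__ = [
    "FormatError",
    "TRAJECTORY_COLUMNS",
    "KICK_COLUMNS",
    "read_trajectory",
    "write_trajectory",
    "read_kicks",
    "write_kicks",
    "write_fit_json",
    "read_fit_json",
    "load_params",
    "load_params_file",
    "save_params_file",
    "available_conditions",
    "summarize_file",
]

TRAJECTORY_COLUMNS = ["frame", "time_s", "fish_id", "x_mm", "y_mm",
                      "heading_rad"]
KICK_COLUMNS = ["fish_id", "t_start", "tau_s", "length_mm", "v_peak"]

LIGHT_LABELS = (0.5, 1.0, 1.5, 5.0, 50.0)
GROUP_SIZES = (1, 2, 5, 25)


class FormatError(ValueError):
    """A file does not match its declared dialect."""


def _check_columns(df: pd.DataFrame, required: Iterable[str],
                   what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing columns {missing}; "
                          f"found {list(df.columns)}")


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, TRAJECTORY_COLUMNS[:5], "trajectory file")
    return df


def write_trajectory(df: pd.DataFrame, path) -> None:
    _check_columns(df, TRAJECTORY_COLUMNS[:5], "trajectory table")
    df.to_csv(path, index=False)


def read_kicks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["fish_id", "t_start"], "kick file")
    return df


def write_kicks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_fit_json(fit: FitResult, path) -> None:
    payload = {"params": fit.params, "residual": fit.residual,
               "stderr": fit.stderr, "converged": fit.converged,
               "weight_outside": fit.weight_outside}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    return FitResult(params=d["params"], residual=d["residual"],
                     stderr=d["stderr"], converged=d["converged"],
                     weight_outside=d.get("weight_outside", 0.0))


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------

def _condition_filename(n_fish: int, label: float) -> str:
    lab = f"{label:g}".replace(".", "p")
    return f"n{n_fish}_lx{lab}.yaml"


def available_conditions() -> List[Tuple[int, float]]:
    """(group size, light label) pairs with packaged defaults."""
    return [(n, l) for n in GROUP_SIZES for l in LIGHT_LABELS]


def load_params_file(path) -> LightParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"parameter file {path} is not a key-value map")
    return LightParams.from_dict(data)


def save_params_file(p: LightParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=False)


def load_params(n_fish: int, label: float) -> LightParams:
    """Packaged default parameter vector for a (group size, light) pair."""
    name = _condition_filename(n_fish, label)
    pkg = resources.files("burstcoast") / "params" / name
    if not pkg.is_file():
        opts = ", ".join(f"(N={n}, {l:g} lx)"
                         for n, l in available_conditions())
        raise FormatError(
            f"no packaged parameters for N={n_fish}, {label:g} lx; "
            f"available conditions: {opts}")
    data = yaml.safe_load(pkg.read_text())
    return LightParams.from_dict(data)


# ---------------------------------------------------------------------------
# streamed observables
# ---------------------------------------------------------------------------

def summarize_file(path, arena: Arena = Arena(),
                   frames_per_block: int = 2000,
                   rows_per_chunk: int = 200_000) -> dict:
    """Time-averaged observables of a trajectory CSV, streamed in blocks of
    complete frames so arbitrarily long recordings fit in memory.

    Blocks overlap by two frames so the centered finite differences used
    for velocities match an in-memory evaluation exactly.
    """
    reader = pd.read_csv(path, chunksize=rows_per_chunk)
    buffer = pd.DataFrame()
    carry = pd.DataFrame()
    sums = {"D_mm": 0.0, "P": 0.0, "M": 0.0}
    n_frames_done = 0
    fish_sums = {"r_w_mm": 0.0, "nnd_mm": 0.0}
    n_fish_rows = 0
    nnd_any = False
    global_first_done = False

    def _process(block: pd.DataFrame, commit_frames: np.ndarray) -> None:
        nonlocal n_frames_done, n_fish_rows, nnd_any
        obs = evaluate_trajectory(block, arena)
        ft = obs.frame_table[obs.frame_table["frame"].isin(commit_frames)]
        for key in sums:
            sums[key] += float(ft[key].sum())
        n_frames_done += len(ft)
        fi = obs.fish_table[obs.fish_table["frame"].isin(commit_frames)]
        fish_sums["r_w_mm"] += float(fi["r_w_mm"].sum())
        if fi["nnd_mm"].notna().any():
            fish_sums["nnd_mm"] += float(fi["nnd_mm"].sum())
            nnd_any = True
        n_fish_rows += len(fi)

    for chunk in reader:
        _check_columns(chunk, TRAJECTORY_COLUMNS[:5], "trajectory file")
        buffer = pd.concat([buffer, chunk], ignore_index=True)
        frames = buffer["frame"].unique()
        # the last frame in the buffer may still be partial
        while len(frames) > frames_per_block + 2:
            take = frames[:frames_per_block + 2]
            block = pd.concat(
                [carry, buffer[buffer["frame"].isin(take)]],
                ignore_index=True)
            commit = np.setdiff1d(take[:-2],
                                  carry["frame"].unique()
                                  if len(carry) else [])
            _process(block, commit)
            global_first_done = True
            carry = buffer[buffer["frame"].isin(take[-4:-2])]
            buffer = buffer[~buffer["frame"].isin(take[:-2])]
            frames = buffer["frame"].unique()
    # final block: everything left (plus halo) is committed
    if len(buffer):
        block = pd.concat([carry, buffer], ignore_index=True)
        commit = np.setdiff1d(buffer["frame"].unique(),
                              carry["frame"].unique() if len(carry) else [])
        if not global_first_done:
            commit = buffer["frame"].unique()
        _process(block, commit)

    if n_frames_done == 0:
        raise FormatError("empty trajectory file")
    return {
        "r_w_mm": fish_sums["r_w_mm"] / n_fish_rows,
        "nnd_mm": (fish_sums["nnd_mm"] / n_fish_rows) if nnd_any
        else float("nan"),
        "D_mm": sums["D_mm"] / n_frames_done,
        "P": sums["P"] / n_frames_done,
        "M": sums["M"] / n_frames_done,
    }
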