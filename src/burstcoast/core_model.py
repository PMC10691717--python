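"""Domain types, angle conventions, and analytic interaction functions.

The model describes rummy-nose tetra (*Hemigrammus rhodostomus*) swimming in
a circular arena with a burst-and-coast gait: at each "kick" a fish picks a
new heading and glides along a straight segment with quasi-exponentially
decaying speed.  The heading change at a kick is the additive combination of

* a spontaneous Gaussian term whose amplitude is reduced near the wall,
* a wall-repulsion term ``f_w(r_w) * O_w(theta_w)``,
* pairwise social terms (attraction + alignment), each a decoupled product
  of a radial intensity and two angular modulations.

Angle conventions
-----------------
Headings ``phi`` are measured counter-clockwise from +x.  With ``theta`` the
polar angle of the fish position,

* ``theta_w = wrap(phi - theta)``  -- 0 means heading radially outward,
  +/- pi/2 means swimming tangentially;
* ``psi    = wrap(bearing(focal -> neighbor) - phi_focal)`` -- viewing angle
  of the neighbor, positive counter-clockwise;
* ``delta_phi = wrap(phi_neighbor - phi_focal)`` -- relative orientation.

A positive heading change ``dphi`` is a counter-clockwise turn.  All angular
modulation functions are normalized so that the mean of their square over
``(-pi, pi]`` equals 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from functools import lru_cache
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad

__all__ = [
    "Arena",
    "LightParams",
    "WallState",
    "PairState",
    "wrap_angle",
    "normalize_angular",
    "wall_force",
    "wall_angular",
    "attraction_odd",
    "attraction_even",
    "alignment_odd",
    "alignment_even",
    "attraction_dphi",
    "alignment_dphi",
    "social_dphi",
    "spontaneous_dphi",
]

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Arena:
    """Circular tank of radius ``R`` (mm)."""

    R: float = 250.0

    def __post_init__(self) -> None:
        if not (self.R > 0):
            raise ValueError(f"arena radius must be positive, got {self.R}")


@dataclass
class LightParams:
    """Full parameter vector of the model for one light condition.

    Units: lengths in mm, times in s, angles in rad.  ``gamma_att``,
    ``gamma_ali`` and ``gamma_m`` are dimensionless intensities; the angular
    factors they multiply are normalized to unit mean square.

    ``l_w`` is the wall-repulsion range; it also sets the scale of the
    near-wall reduction of the spontaneous noise unless ``l_w_noise``
    overrides it (the two ranges share a symbol in the model but are fitted
    from the same single-fish data, so one value is the default).
    """

    label: float                      # light level, lx
    gamma_R: float                    # spontaneous heading-noise sd, rad
    alpha: float                      # near-wall noise reduction, (0, 1)
    gamma_w: float                    # wall repulsion intensity, rad
    l_w: float                        # wall repulsion range, mm
    tau0: float                       # gliding speed decay time, s
    tau_bar: float                    # mean kick duration (untruncated), s
    tau_min: float                    # kick-duration resampling threshold, s
    v_bar: float                      # mean peak speed (untruncated), mm/s
    gamma_att: float                  # attraction intensity
    l_att: float                      # attraction range, mm
    d_att: float                      # attraction sign-change distance, mm
    gamma_ali: float                  # alignment intensity
    l_ali: float                      # alignment range, mm
    d_ali: float                      # alignment fixed scale, mm
    gamma_m: float                    # kick-length modulation intensity
    l_m: float                        # kick-length saturation value, mm
    d_m: float                        # kick-length modulation offset, mm
    l_c: float                        # comfort distance to the wall, mm
    l_bar: float                      # mean kick length for N >= 5 groups, mm
    k: int = 2                        # number of most influential neighbors
    v_min: float = 0.0                # peak-speed resampling threshold, mm/s
    l_w_noise: Optional[float] = None  # override range for the noise reduction

    def __post_init__(self) -> None:
        for name in ("l_w", "tau0", "tau_bar", "v_bar", "l_att", "d_att",
                     "l_ali", "d_ali", "l_m", "l_c", "l_bar"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (self.tau_bar > self.tau_min >= 0.0):
            raise ValueError("need tau_bar > tau_min >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.l_w_noise is not None and not (self.l_w_noise > 0):
            raise ValueError("l_w_noise must be > 0 when set")

    @property
    def noise_range(self) -> float:
        """Range of the near-wall noise reduction (``l_w`` unless overridden)."""
        return self.l_w if self.l_w_noise is None else self.l_w_noise

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["l_w_noise"] is None:
            d.pop("l_w_noise")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LightParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class WallState:
    """State of a fish relative to the wall: distance ``r_w = R - |u|`` (mm)
    and relative orientation ``theta_w`` in ``(-pi, pi]``."""

    r_w: float
    theta_w: float


@dataclass(frozen=True)
class PairState:
    """Relative state of a neighbor seen from a focal fish: distance ``d``
    (mm), viewing angle ``psi`` and relative orientation ``delta_phi``
    (rad, wrapped to ``(-pi, pi]``)."""

    d: float
    psi: float
    delta_phi: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("pair distance must be >= 0")


# ---------------------------------------------------------------------------
# angles and normalization
# ---------------------------------------------------------------------------

def wrap_angle(a):
    """Wrap angle(s) to ``(-pi, pi]``.

    Accepts scalars or arrays; the branch cut maps odd multiples of pi to
    ``+pi``.  Non-finite input is rejected.
    """
    arr = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = math.pi - np.mod(math.pi - arr, TWO_PI)
    if np.isscalar(a) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


def normalize_angular(f: Callable[[float], float], *, epsabs: float = 1e-10) -> float:
    """Normalization constant ``A`` such that ``(1/2pi) int (A f)^2 = 1``.

    The integral over ``(-pi, pi]`` is done by adaptive quadrature.  Raises
    for an (numerically) identically-zero function.
    """
    integral, _ = quad(lambda t: f(t) ** 2, -math.pi, math.pi,
                       epsabs=epsabs, limit=200)
    mean_square = integral / TWO_PI
    if mean_square <= 1e-15:
        raise ValueError("cannot normalize an identically-zero function")
    return 1.0 / math.sqrt(mean_square)


# Raw (unnormalized) angular shapes.  The cosine coefficients are the fitted
# shapes shared by all light conditions; intensities live in LightParams.

def _raw_wall_angular(t):
    return np.sin(t) * (1.0 + 0.8 * np.cos(2.0 * t))


def _raw_attraction_odd(psi):
    return np.sin(psi) * (1.0 - 0.33 * np.cos(psi))


def _raw_attraction_even(dphi):
    return 1.0 - 0.6 * np.cos(dphi) - 0.4 * np.cos(2.0 * dphi)


def _raw_alignment_odd(dphi):
    return np.sin(dphi) * (1.0 + 0.33 * np.cos(dphi))


def _raw_alignment_even(psi):
    return 1.0 + 1.18 * np.cos(psi) - 0.49 * np.cos(2.0 * psi)


_RAW = {
    "wall_angular": _raw_wall_angular,
    "attraction_odd": _raw_attraction_odd,
    "attraction_even": _raw_attraction_even,
    "alignment_odd": _raw_alignment_odd,
    "alignment_even": _raw_alignment_even,
}


@lru_cache(maxsize=None)
def _norm_const(name: str) -> float:
    return normalize_angular(_RAW[name])


def wall_angular(theta_w):
    """Normalized odd wall modulation ``O_w(theta_w)``."""
    return _norm_const("wall_angular") * _raw_wall_angular(theta_w)


def attraction_odd(psi):
    """Normalized odd attraction modulation ``O_Att(psi)``."""
    return _norm_const("attraction_odd") * _raw_attraction_odd(psi)


def attraction_even(dphi):
    """Normalized even attraction modulation ``E_Att(delta_phi)``."""
    return _norm_const("attraction_even") * _raw_attraction_even(dphi)


def alignment_odd(dphi):
    """Normalized odd alignment modulation ``O_Ali(delta_phi)``."""
    return _norm_const("alignment_odd") * _raw_alignment_odd(dphi)


def alignment_even(psi):
    """Normalized even alignment modulation ``E_Ali(psi)``."""
    return _norm_const("alignment_even") * _raw_alignment_even(psi)


# ---------------------------------------------------------------------------
# interaction terms
# ---------------------------------------------------------------------------

def wall_force(r_w, p: LightParams):
    """Radial intensity of the wall repulsion, ``gamma_w exp[-(r_w/l_w)^2]``.

    Positive and strictly decreasing in the distance to the wall.
    """
    r = np.asarray(r_w, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance to wall must be >= 0")
    out = p.gamma_w * np.exp(-((r / p.l_w) ** 2))
    return float(out) if out.ndim == 0 else out


def attraction_radial(d, p: LightParams):
    """``f_Att(d) = gamma_att (d/d_att - 1) / (1 + (d/l_att)^2)``.

    Changes sign at ``d = d_att`` (repulsive below, attractive above).
    """
    d = np.asarray(d, dtype=float)
    out = p.gamma_att * (d / p.d_att - 1.0) / (1.0 + (d / p.l_att) ** 2)
    return float(out) if out.ndim == 0 else out


def alignment_radial(d, p: LightParams):
    """``f_Ali(d) = gamma_ali (d/d_ali) exp[-(d/l_ali)^2]``.

    Vanishes at contact and is maximal at ``d = l_ali / sqrt(2)``.
    """
    d = np.asarray(d, dtype=float)
    out = p.gamma_ali * (d / p.d_ali) * np.exp(-((d / p.l_ali) ** 2))
    return float(out) if out.ndim == 0 else out


def _attraction_arrays(d, psi, dphi, p: LightParams):
    return attraction_radial(d, p) * attraction_odd(psi) * attraction_even(dphi)


def _alignment_arrays(d, psi, dphi, p: LightParams):
    return alignment_radial(d, p) * alignment_odd(dphi) * alignment_even(psi)


def _social_arrays(d, psi, dphi, p: LightParams):
    return _attraction_arrays(d, psi, dphi, p) + _alignment_arrays(d, psi, dphi, p)


def attraction_dphi(s: PairState, p: LightParams) -> float:
    """Attraction contribution to the heading change (rad)."""
    return float(_attraction_arrays(s.d, s.psi, s.delta_phi, p))


def alignment_dphi(s: PairState, p: LightParams) -> float:
    """Alignment contribution to the heading change (rad)."""
    return float(_alignment_arrays(s.d, s.psi, s.delta_phi, p))


def social_dphi(s: PairState, p: LightParams) -> float:
    """Total pairwise social contribution: attraction plus alignment."""
    return attraction_dphi(s, p) + alignment_dphi(s, p)


def noise_sd(r_w, p: LightParams):
    """Standard deviation of the spontaneous heading change at distance
    ``r_w`` from the wall: ``gamma_R (1 - alpha exp[-(r_w/l_w)^2])``."""
    r = np.asarray(r_w, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance to wall must be >= 0")
    lw = p.noise_range
    out = p.gamma_R * (1.0 - p.alpha * np.exp(-((r / lw) ** 2)))
    return float(out) if out.ndim == 0 else out


def spontaneous_dphi(r_w, p: LightParams, rng: np.random.Generator):
    """Draw spontaneous heading change(s), zero-mean Gaussian with the
    wall-reduced standard deviation of :func:`noise_sd`."""
    sd = noise_sd(r_w, p)
    g = rng.standard_normal(size=np.shape(sd) if np.ndim(sd) else None)
    out = sd * g
    return float(out) if np.ndim(out) == 0 else out
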