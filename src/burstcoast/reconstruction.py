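"""Recover interaction functions and model parameters from kick tables.

The procedure mirrors the data-analysis chain used to calibrate the model:

1. bin the per-kick heading changes ``dphi`` against the state variables
   (wall state ``(r_w, theta_w)`` for a single fish, pair state
   ``(d, psi, delta_phi)`` for two fish);
2. project out the component with the parity of the sought interaction
   (wall and attraction are odd in their angle arguments, alignment odd in
   ``delta_phi``), which cancels symmetric noise;
3. factor the binned array into a product of a radial intensity and
   normalized angular modulations (masked alternating least squares);
4. fit the analytic forms of the model to the discrete factors
   (multi-start nonlinear least squares).

Angular factors carry the unit-mean-square normalization; the intensity and
overall scale live in the radial factor, matching the conventions of
:mod:`burstcoast.core_model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import binned_statistic_2d, binned_statistic_dd

__all__ = [
    "BinnedInteraction",
    "FitResult",
    "fit_gamma_R",
    "fit_tau0",
    "bin_wall_interaction",
    "extract_wall_product",
    "fit_wall_params",
    "extract_social",
    "fit_social_params",
    "fit_modulation",
]

DEFAULT_R_BIN_MM = 10.0
DEFAULT_N_ANGLE_BINS = 16
DEFAULT_MIN_COUNT = 50
WALL_EXCLUDE_MM = 60.0     # social extraction ignores kicks closer to the wall
WALL_FIT_RMAX_MM = 80.0    # wall-intensity fit range (sparse data beyond)


@dataclass
class BinnedInteraction:
    """Discrete interaction estimate on a rectangular grid."""

    edges: Tuple[np.ndarray, ...]
    mean: np.ndarray           # per-bin mean dphi; NaN where invalid
    count: np.ndarray
    se: np.ndarray             # standard error of the mean; NaN where invalid

    @property
    def centers(self) -> Tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.mean)


@dataclass
class FitResult:
    """Fitted parameters with convergence diagnostics."""

    params: Dict[str, float]
    residual: float
    stderr: Dict[str, float]
    converged: bool
    weight_outside: float = 0.0   # data fraction outside the fitted range

    def __getitem__(self, key: str) -> float:
        return self.params[key]


# ---------------------------------------------------------------------------
# scalar fits
# ---------------------------------------------------------------------------

def fit_gamma_R(kicks: pd.DataFrame, r_w_min: float = WALL_EXCLUDE_MM,
                dphi_col: str = "dphi") -> FitResult:
    """Spontaneous heading-noise intensity from kicks far from the wall.

    Far from the wall the heading change is (near) pure Gaussian noise, so
    ``gamma_R`` is estimated as the standard deviation of ``dphi`` over
    kicks with ``r_w > r_w_min`` (60 mm by default, the distance at which
    the wall influence becomes negligible).
    """
    sel = kicks.loc[kicks["r_w_mm"] > r_w_min, dphi_col].to_numpy()
    if sel.size < 2:
        raise ValueError("not enough kicks far from the wall")
    sd = float(np.std(sel, ddof=1))
    # sd of the sd estimate for a Gaussian sample
    se = sd / math.sqrt(2.0 * (sel.size - 1))
    return FitResult({"gamma_R": sd}, residual=0.0,
                     stderr={"gamma_R": se}, converged=True)


def fit_tau0(t: np.ndarray, v_norm: np.ndarray) -> FitResult:
    """Glide decay time from a speed profile normalized at the kick instant.

    Fits ``exp(-t/tau0)`` by nonlinear least squares.  Nonpositive speeds
    are rejected (the glide speed is strictly positive).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v_norm, dtype=float)
    if np.any(v <= 0):
        raise ValueError("speed profile must be strictly positive")
    # log-linear start, then least squares on the linear scale
    slope = np.polyfit(t, np.log(v), 1)[0]
    tau_init = -1.0 / slope if slope < 0 else 1.0
    res = least_squares(lambda p: np.exp(-t / p[0]) - v, x0=[tau_init],
                        bounds=([1e-6], [np.inf]))
    tau0 = float(res.x[0])
    return FitResult({"tau0": tau0}, residual=float(np.sum(res.fun ** 2)),
                     stderr={"tau0": float("nan")}, converged=res.success)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _angle_edges(n: int = DEFAULT_N_ANGLE_BINS) -> np.ndarray:
    return np.linspace(-math.pi, math.pi, n + 1)


def _masked(stat: np.ndarray, count: np.ndarray, sumsq: np.ndarray,
            min_count: int):
    mean = np.where(count >= min_count, stat, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = sumsq / np.maximum(count, 1) - stat ** 2
        se = np.sqrt(np.maximum(var, 0.0) / np.maximum(count, 1))
    se = np.where(count >= min_count, se, np.nan)
    return mean, se


def bin_wall_interaction(kicks: pd.DataFrame,
                         r_edges: Optional[np.ndarray] = None,
                         n_angle_bins: int = DEFAULT_N_ANGLE_BINS,
                         min_count: int = DEFAULT_MIN_COUNT,
                         dphi_col: str = "dphi") -> BinnedInteraction:
    """Mean heading change on an ``(r_w, theta_w)`` grid (single fish)."""
    r = kicks["r_w_mm"].to_numpy()
    th = kicks["theta_w_rad"].to_numpy()
    dphi = kicks[dphi_col].to_numpy()
    if r_edges is None:
        r_edges = np.arange(0.0, min(r.max(), 120.0) + DEFAULT_R_BIN_MM,
                            DEFAULT_R_BIN_MM)
    t_edges = _angle_edges(n_angle_bins)
    mean, _, _, _ = binned_statistic_2d(r, th, dphi, "mean",
                                        bins=[r_edges, t_edges])
    count, _, _, _ = binned_statistic_2d(r, th, dphi, "count",
                                         bins=[r_edges, t_edges])
    sumsq, _, _, _ = binned_statistic_2d(r, th, dphi ** 2, "sum",
                                         bins=[r_edges, t_edges])
    mean_m, se = _masked(mean, count, sumsq, min_count)
    return BinnedInteraction(edges=(r_edges, t_edges), mean=mean_m,
                             count=count, se=se)


# ---------------------------------------------------------------------------
# product decomposition
# ---------------------------------------------------------------------------

def _antisymmetrize_last(mean: np.ndarray) -> np.ndarray:
    """Odd part along the last (angular) axis of a uniform (-pi, pi] grid:
    bin i mirrors to bin n-1-i."""
    flipped = mean[..., ::-1]
    return 0.5 * (mean - flipped)


def _rank1_2d(M: np.ndarray, W: np.ndarray, tol: float = 1e-8,
              max_iter: int = 500) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Weighted rank-1 factorization ``M ~ f o^T`` with missing data.

    Initialized from the (absolute) marginal row means; iterated to a fixed
    point.  NaNs in M must have zero weight in W.
    """
    Mz = np.nan_to_num(M)
    o = np.nansum(np.abs(M) * W, axis=0)
    o = o / (np.linalg.norm(o) + 1e-300)
    f = np.zeros(M.shape[0])
    converged = False
    for _ in range(max_iter):
        denom = W @ (o ** 2)
        f_new = (Mz * W) @ o / np.where(denom > 0, denom, np.nan)
        f_new = np.nan_to_num(f_new)
        denom = W.T @ (f_new ** 2)
        o_new = (Mz * W).T @ f_new / np.where(denom > 0, denom, np.nan)
        o_new = np.nan_to_num(o_new)
        norm = np.linalg.norm(o_new)
        if norm == 0:
            break
        f_new = f_new * norm
        o_new = o_new / norm
        if (np.max(np.abs(f_new - f)) < tol
                and np.max(np.abs(o_new - o)) < tol):
            f, o = f_new, o_new
            converged = True
            break
        f, o = f_new, o_new
    return f, o, converged


def _normalize_angular_discrete(o: np.ndarray, odd_like_sin: bool,
                                centers: np.ndarray):
    """Rescale a discrete angular factor to unit mean square over the grid
    and fix its sign; returns (factor, scale absorbed by the radial part)."""
    rms = math.sqrt(float(np.mean(o ** 2)))
    if rms == 0:
        raise ValueError("degenerate angular factor")
    o = o / rms
    ref = np.sin(centers) if odd_like_sin else np.ones_like(centers)
    sign = 1.0 if float(np.dot(o, ref)) >= 0 else -1.0
    return o * sign, rms * sign


def extract_wall_product(bins: BinnedInteraction):
    """Decompose the antisymmetrized wall grid into ``f_w(r_w) O_w(theta_w)``.

    Returns ``(r_centers, f_w, theta_centers, O_w, converged)`` with the
    unit-mean-square convention on ``O_w``.  Raises when no grid row has
    enough occupancy.
    """
    A = _antisymmetrize_last(bins.mean)
    W = np.where(bins.valid & bins.valid[..., ::-1],
                 np.minimum(bins.count, bins.count[..., ::-1]), 0.0)
    if not np.any(W.sum(axis=1) > 0):
        raise ValueError("insufficient occupancy for wall extraction")
    A = np.where(W > 0, A, np.nan)
    f, o, converged = _rank1_2d(A, W)
    r_centers, t_centers = bins.centers
    o, scale = _normalize_angular_discrete(o, odd_like_sin=True,
                                           centers=t_centers)
    f = f * scale
    return r_centers, f, t_centers, o, converged


# ---------------------------------------------------------------------------
# analytic fits
# ---------------------------------------------------------------------------

def _multistart_ls(residual_fn, starts: Sequence[Sequence[float]],
                   bounds) -> Tuple[np.ndarray, float, bool]:
    best_x, best_cost, ok = None, np.inf, False
    for x0 in starts:
        try:
            res = least_squares(residual_fn, x0=np.asarray(x0, float),
                                bounds=bounds)
        except ValueError:
            continue
        if res.cost < best_cost:
            best_x, best_cost, ok = res.x, res.cost, res.success
    if best_x is None:
        raise RuntimeError("all fit starts failed")
    return best_x, best_cost, ok


def fit_wall_params(r_centers: np.ndarray, f_vals: np.ndarray,
                    counts: Optional[np.ndarray] = None,
                    r_max: float = WALL_FIT_RMAX_MM) -> FitResult:
    """Fit ``gamma_w exp[-(r_w/l_w)^2]`` to the discrete wall intensity.

    Restricted to ``r_w <= r_max`` (80 mm by default): the occupancy
    beyond is a small residual and the discrete values there fluctuate.
    The weight of the excluded data is reported.
    """
    r = np.asarray(r_centers, float)
    f = np.asarray(f_vals, float)
    good = np.isfinite(f)
    inside = good & (r <= r_max)
    if counts is not None:
        tot = float(np.sum(counts[good]))
        weight_outside = float(np.sum(counts[good & (r > r_max)])) / tot \
            if tot > 0 else 0.0
    else:
        weight_outside = float(np.sum(good & (r > r_max))) / \
            max(float(np.sum(good)), 1.0)
    r_in, f_in = r[inside], f[inside]
    if r_in.size < 3:
        raise ValueError("too few valid bins inside the fit range")

    def resid(p):
        return p[0] * np.exp(-((r_in / p[1]) ** 2)) - f_in

    f0 = max(float(np.max(np.abs(f_in))), 1e-6)
    starts = [(g, l) for g in (0.5 * f0, f0, 2.0 * f0)
              for l in (20.0, 40.0, 60.0, 90.0)]
    x, cost, ok = _multistart_ls(resid, starts,
                                 ([1e-9, 1.0], [np.inf, 1e4]))
    return FitResult({"gamma_w": float(x[0]), "l_w": float(x[1])},
                     residual=float(cost),
                     stderr={"gamma_w": float("nan"), "l_w": float("nan")},
                     converged=ok, weight_outside=weight_outside)


# ---------------------------------------------------------------------------
# social extraction (pairs)
# ---------------------------------------------------------------------------

def _rank1_3d(T: np.ndarray, W: np.ndarray, tol: float = 1e-8,
              max_iter: int = 500):
    """Weighted rank-1 factorization ``T ~ f x o x e`` with missing data."""
    Tz = np.nan_to_num(T)
    o = np.nansum(np.abs(T) * W, axis=(0, 2))
    o = o / (np.linalg.norm(o) + 1e-300)
    e = np.nansum(np.abs(T) * W, axis=(0, 1))
    e = e / (np.linalg.norm(e) + 1e-300)
    f = np.zeros(T.shape[0])
    converged = False
    for _ in range(max_iter):
        oe = o[:, None] * e[None, :]
        denom = np.einsum("ijk,jk->i", W, oe ** 2)
        f_new = np.einsum("ijk,jk->i", Tz * W, oe)
        f_new = np.nan_to_num(f_new / np.where(denom > 0, denom, np.nan))
        fe = f_new[:, None] * e[None, :]
        denom = np.einsum("ijk,ik->j", W, fe ** 2)
        o_new = np.einsum("ijk,ik->j", Tz * W, fe)
        o_new = np.nan_to_num(o_new / np.where(denom > 0, denom, np.nan))
        fo = f_new[:, None] * o_new[None, :]
        denom = np.einsum("ijk,ij->k", W, fo ** 2)
        e_new = np.einsum("ijk,ij->k", Tz * W, fo)
        e_new = np.nan_to_num(e_new / np.where(denom > 0, denom, np.nan))
        no, ne = np.linalg.norm(o_new), np.linalg.norm(e_new)
        if no == 0 or ne == 0:
            break
        f_new = f_new * no * ne
        o_new, e_new = o_new / no, e_new / ne
        if (np.max(np.abs(f_new - f)) < tol
                and np.max(np.abs(o_new - o)) < tol
                and np.max(np.abs(e_new - e)) < tol):
            f, o, e = f_new, o_new, e_new
            converged = True
            break
        f, o, e = f_new, o_new, e_new
    return f, o, e, converged


def _parity_project(mean: np.ndarray, axis_odd: int, axis_even: int):
    """Four-term symmetrization isolating the component odd along
    ``axis_odd`` and even along ``axis_even`` (uniform angle grids)."""
    flip_odd = np.flip(mean, axis=axis_odd)
    flip_even = np.flip(mean, axis=axis_even)
    flip_both = np.flip(flip_odd, axis=axis_even)
    return 0.25 * (mean - flip_odd + flip_even - flip_both)


def extract_social(kicks: pd.DataFrame,
                   d_edges: Optional[np.ndarray] = None,
                   n_angle_bins: int = DEFAULT_N_ANGLE_BINS,
                   min_count: int = DEFAULT_MIN_COUNT,
                   r_w_exclude: float = WALL_EXCLUDE_MM,
                   dphi_col: str = "dphi") -> dict:
    """Discrete social interaction factors from a two-fish kick table.

    Kicks closer than ``r_w_exclude`` to the wall are ignored so the wall
    term does not contaminate the social estimate.  The attraction
    component is the part of the binned ``dphi`` odd in ``psi`` and even in
    ``delta_phi``; alignment is odd in ``delta_phi`` and even in ``psi``.
    Each component is factored into radial x odd x even parts with the
    package's normalization convention.

    Returns a dict with keys ``d_centers``, ``psi_centers``,
    ``dphi_centers``, ``f_att``, ``o_att``, ``e_att``, ``f_ali``,
    ``o_ali``, ``e_ali``, ``bins`` and ``converged``.
    """
    t = kicks
    if "r_w_mm" in t.columns:
        t = t[t["r_w_mm"] > r_w_exclude]
    t = t.dropna(subset=["d_mm", "psi_rad", "delta_phi_rad", dphi_col])
    if t.empty:
        raise ValueError("no usable kicks for social extraction")
    d = t["d_mm"].to_numpy()
    psi = t["psi_rad"].to_numpy()
    dph = t["delta_phi_rad"].to_numpy()
    y = t[dphi_col].to_numpy()
    if d_edges is None:
        d_edges = np.arange(0.0, min(d.max(), 200.0) + DEFAULT_R_BIN_MM,
                            DEFAULT_R_BIN_MM)
    a_edges = _angle_edges(n_angle_bins)
    sample = np.stack([d, psi, dph], axis=1)
    bins = [d_edges, a_edges, a_edges]
    mean, _, _ = binned_statistic_dd(sample, y, "mean", bins=bins)
    count, _, _ = binned_statistic_dd(sample, y, "count", bins=bins)
    sumsq, _, _ = binned_statistic_dd(sample, y ** 2, "sum", bins=bins)
    mean_m, se = _masked(mean, count, sumsq, min_count)

    # a bin participates only when its full parity orbit is occupied
    orbit_ok = np.isfinite(mean_m)
    for ax in (1, 2):
        orbit_ok = orbit_ok & np.flip(orbit_ok, axis=ax)
    orbit_ok = orbit_ok & np.flip(np.flip(orbit_ok, axis=1), axis=2)
    if not orbit_ok.any():
        raise ValueError("insufficient occupancy for social extraction")
    filled = np.where(orbit_ok, np.nan_to_num(mean_m), np.nan)
    # parity-symmetric weights keep the factorized components exactly
    # odd/even: use the orbit minimum of the counts
    W = np.where(orbit_ok, count, 0.0)
    for ax in (1, 2):
        W = np.minimum(W, np.flip(W, axis=ax))
    W = np.minimum(W, np.flip(np.flip(W, axis=1), axis=2))

    att = _parity_project(np.nan_to_num(filled), axis_odd=1, axis_even=2)
    ali = _parity_project(np.nan_to_num(filled), axis_odd=2, axis_even=1)
    att = np.where(orbit_ok, att, np.nan)
    ali = np.where(orbit_ok, ali, np.nan)

    d_centers = 0.5 * (d_edges[1:] + d_edges[:-1])
    a_centers = 0.5 * (a_edges[1:] + a_edges[:-1])

    f_att, o_att, e_att, c1 = _rank1_3d(att, W)
    o_att, s = _normalize_angular_discrete(o_att, True, a_centers)
    f_att = f_att * s
    e_att, s = _normalize_angular_discrete(e_att, False, a_centers)
    f_att = f_att * s

    # alignment: odd factor lives on delta_phi (axis 2), even on psi (axis 1)
    ali_t = np.transpose(ali, (0, 2, 1))
    W_t = np.transpose(W, (0, 2, 1))
    f_ali, o_ali, e_ali, c2 = _rank1_3d(ali_t, W_t)
    o_ali, s = _normalize_angular_discrete(o_ali, True, a_centers)
    f_ali = f_ali * s
    e_ali, s = _normalize_angular_discrete(e_ali, False, a_centers)
    f_ali = f_ali * s

    binned = BinnedInteraction(edges=(d_edges, a_edges, a_edges),
                               mean=mean_m, count=count, se=se)
    return {
        "d_centers": d_centers, "psi_centers": a_centers,
        "dphi_centers": a_centers,
        "f_att": f_att, "o_att": o_att, "e_att": e_att,
        "f_ali": f_ali, "o_ali": o_ali, "e_ali": e_ali,
        "bins": binned, "converged": bool(c1 and c2),
    }


def fit_social_params(d_centers: np.ndarray, f_att: np.ndarray,
                      f_ali: np.ndarray, d_ali: float,
                      d_max: Optional[float] = None) -> FitResult:
    """Fit the analytic radial forms to the discrete social intensities.

    Attraction: ``gamma_att (d/d_att - 1) / (1 + (d/l_att)^2)``;
    alignment: ``gamma_ali (d/d_ali) exp[-(d/l_ali)^2]`` with ``d_ali``
    held fixed (it is an arbitrary scale).
    """
    d = np.asarray(d_centers, float)
    fa = np.asarray(f_att, float)
    fl = np.asarray(f_ali, float)
    sel = np.isfinite(fa) & np.isfinite(fl)
    if d_max is not None:
        sel = sel & (d <= d_max)
    d_s, fa_s, fl_s = d[sel], fa[sel], fl[sel]
    if d_s.size < 4:
        raise ValueError("too few valid distance bins")

    def resid_att(p):
        g, l, da = p
        return g * (d_s / da - 1.0) / (1.0 + (d_s / l) ** 2) - fa_s

    g0 = max(float(np.max(np.abs(fa_s))), 1e-6)
    starts = [(g, l, da) for g in (0.5 * g0, g0, 2 * g0)
              for l in (50.0, 120.0, 250.0) for da in (15.0, 30.0, 60.0)]
    xa, ca, oka = _multistart_ls(resid_att, starts,
                                 ([1e-9, 1.0, 1.0], [np.inf, 2e3, 500.0]))

    def resid_ali(p):
        g, l = p
        return g * (d_s / d_ali) * np.exp(-((d_s / l) ** 2)) - fl_s

    g1 = max(float(np.max(np.abs(fl_s))), 1e-6)
    starts = [(g, l) for g in (0.5 * g1, g1, 2 * g1)
              for l in (50.0, 120.0, 250.0)]
    xl, cl, okl = _multistart_ls(resid_ali, starts,
                                 ([1e-9, 1.0], [np.inf, 2e3]))
    return FitResult(
        {"gamma_att": float(xa[0]), "l_att": float(xa[1]),
         "d_att": float(xa[2]),
         "gamma_ali": float(xl[0]), "l_ali": float(xl[1]), "d_ali": d_ali},
        residual=float(ca + cl),
        stderr={k: float("nan") for k in ("gamma_att", "l_att", "d_att",
                                          "gamma_ali", "l_ali")},
        converged=bool(oka and okl))


def fit_modulation(kicks: pd.DataFrame,
                   d_edges: Optional[np.ndarray] = None,
                   min_count: int = DEFAULT_MIN_COUNT) -> FitResult:
    """Fit the kick-length modulation ``F_m(d) = l_m - gamma_m (d + d_m)
    exp(-d/l_m)`` to binned mean kick lengths of a pair kick table."""
    t = kicks.dropna(subset=["d_mm", "length_mm"])
    d = t["d_mm"].to_numpy()
    ln = t["length_mm"].to_numpy()
    if d_edges is None:
        d_edges = np.arange(0.0, min(d.max(), 250.0) + DEFAULT_R_BIN_MM,
                            DEFAULT_R_BIN_MM)
    idx = np.digitize(d, d_edges) - 1
    nb = len(d_edges) - 1
    means = np.full(nb, np.nan)
    for b in range(nb):
        sel = idx == b
        if np.sum(sel) >= min_count:
            means[b] = float(np.mean(ln[sel]))
    centers = 0.5 * (d_edges[1:] + d_edges[:-1])
    good = np.isfinite(means)
    if np.sum(good) < 4:
        raise ValueError("too few occupied distance bins")
    dc, mc = centers[good], means[good]

    def resid(p):
        lm, gm, dm = p
        return lm - gm * (dc + dm) * np.exp(-dc / lm) - mc

    lm0 = float(np.max(mc))
    starts = [(lm0, g, dm) for g in (0.05, 0.2, 0.5, 1.0)
              for dm in (5.0, 20.0, 60.0)]
    x, cost, ok = _multistart_ls(resid, starts,
                                 ([1.0, 0.0, 0.0], [1e3, 50.0, 500.0]))
    return FitResult({"l_m": float(x[0]), "gamma_m": float(x[1]),
                      "d_m": float(x[2])},
                     residual=float(cost),
                     stderr={k: float("nan") for k in ("l_m", "gamma_m",
                                                       "d_m")},
                     converged=ok)
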