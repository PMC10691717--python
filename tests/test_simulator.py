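"""Kick-event engine: kinematics, samplers, neighbor selection, event loop."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import cumulative_simpson

from burstcoast.core_model import Arena, PairState, social_dphi
from burstcoast.simulator import (
    KickEvent,
    SimulationRun,
    attempt_heading,
    glide_displacement,
    glide_position,
    influence,
    kick_length_from_speed,
    modulated_mean_length,
    run_simulation,
    sample_kick_duration,
    sample_kick_length,
    select_neighbors,
)


def _kick(length=60.0, tau=0.5, heading=0.3, origin=(10.0, -5.0)):
    return KickEvent(0, 0.0, tau, length, float("nan"), origin, heading,
                     0, 0, 0)


def speed_profile(length, tau, tau0, t):
    """Instantaneous glide speed implied by the displacement law."""
    v0 = length / (tau0 * (1 - math.exp(-tau / tau0)))
    return v0 * np.exp(-t / tau0)


class TestGlide:
    def test_endpoints(self):
        k = _kick()
        assert glide_position(k, 0.0, 0.8) == pytest.approx(k.origin)
        x, y = glide_position(k, k.tau, 0.8)
        assert x == pytest.approx(k.origin[0] + k.length * math.cos(k.heading_new))
        assert y == pytest.approx(k.origin[1] + k.length * math.sin(k.heading_new))

    def test_against_speed_integration_oracle(self):
        # displacement must equal the integral of the decaying speed
        length, tau, tau0 = 60.0, 0.5, 0.8
        t = np.linspace(0.0, tau, 501)
        disp_oracle = cumulative_simpson(speed_profile(length, tau, tau0, t),
                                         x=t, initial=0.0)
        disp = glide_displacement(length, tau, t, tau0)
        assert np.allclose(disp, disp_oracle, atol=1e-9)
        assert disp[np.searchsorted(t, 0.25)] == pytest.approx(
            60 * (1 - math.exp(-0.25 / 0.8)) / (1 - math.exp(-0.5 / 0.8)))

    def test_monotone_and_bounds(self):
        k = _kick()
        d = glide_displacement(k.length, k.tau, np.linspace(0, k.tau, 100), 0.8)
        assert np.all(np.diff(d) > 0)
        with pytest.raises(ValueError):
            glide_position(k, -0.01, 0.8)
        with pytest.raises(ValueError):
            glide_position(k, k.tau + 0.01, 0.8)


class TestKickLengthFromSpeed:
    def test_limits(self):
        assert kick_length_from_speed(120, 100.0, 0.8) == pytest.approx(
            120 * 0.8, rel=1e-10)
        assert kick_length_from_speed(120, 1e-6, 0.8) == pytest.approx(
            120 * 1e-6, rel=1e-4)

    def test_against_integration_oracle(self):
        v, tau, tau0 = 120.0, 0.45, 0.8
        t = np.linspace(0, tau, 2001)
        oracle = cumulative_simpson(v * np.exp(-t / tau0), x=t,
                                    initial=0.0)[-1]
        assert kick_length_from_speed(v, tau, tau0) == pytest.approx(
            oracle, rel=1e-8)
        assert kick_length_from_speed(v, tau, tau0) < v * tau0


def truncated_gamma2_mean(mean, floor):
    """E[X | X > floor] for the two-exponential (Gamma shape-2) draw."""
    theta = mean / 2.0
    u = floor / theta
    return theta * (u * u + 2 * u + 2) / (u + 1)


class TestSamplers:
    def test_untruncated_mean(self, harness_params):
        p = harness_params
        d = p.to_dict()
        d["tau_min"] = 0.0
        from burstcoast.core_model import LightParams
        p0 = LightParams.from_dict(d)
        rng = np.random.default_rng(0)
        n = 100_000
        draws = np.array([sample_kick_duration(p0, rng) for _ in range(n)])
        mc_sigma = draws.std() / math.sqrt(n)
        assert abs(draws.mean() - p.tau_bar) < 3 * mc_sigma

    def test_truncation_floor_and_mean(self, harness_params):
        p = harness_params
        rng = np.random.default_rng(1)
        draws = np.array([sample_kick_duration(p, rng) for _ in range(50_000)])
        assert draws.min() >= p.tau_min
        expected = truncated_gamma2_mean(p.tau_bar, p.tau_min)
        mc_sigma = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 4 * mc_sigma

    def test_pair_mode_mean_matches_modulation(self, harness_params):
        p = harness_params
        rng = np.random.default_rng(2)
        d = 45.0
        draws = np.array([sample_kick_length(p, 2, d, rng, tau=0.5)[0]
                          for _ in range(100_000)])
        expected = modulated_mean_length(d, p)
        assert abs(draws.mean() - expected) < 4 * draws.std() / math.sqrt(draws.size)
        assert draws.min() >= 0.0

    def test_single_mode_composition(self, harness_params):
        p = harness_params
        rng = np.random.default_rng(3)
        length, v = sample_kick_length(p, 1, None, rng, tau=0.5)
        assert length == pytest.approx(kick_length_from_speed(v, 0.5, p.tau0))

    def test_mode_errors(self, harness_params):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            sample_kick_length(harness_params, 2, None, rng, tau=0.5)
        with pytest.raises(ValueError):
            sample_kick_length(harness_params, 1, None, rng, tau=None)


class TestModulatedMeanLength:
    def test_closed_forms(self, harness_params):
        p = harness_params
        assert modulated_mean_length(1e7, p) == pytest.approx(p.l_m)
        assert modulated_mean_length(0.0, p) == pytest.approx(
            p.l_m - p.gamma_m * p.d_m)

    def test_stationary_point(self, harness_params):
        p = harness_params
        d = np.linspace(0, 300, 30001)
        f = modulated_mean_length(d, p)
        assert d[np.argmin(f)] == pytest.approx(p.l_m - p.d_m, abs=0.05)

    def test_negative_distance_rejected(self, harness_params):
        with pytest.raises(ValueError):
            modulated_mean_length(-1.0, harness_params)


class TestInfluenceAndSelection:
    def test_influence_matches_social(self, harness_params, rng):
        p = harness_params
        for _ in range(30):
            s = PairState(rng.uniform(1, 300), rng.uniform(-3, 3),
                          rng.uniform(-3, 3))
            assert influence(s, p) == pytest.approx(abs(social_dphi(s, p)))
        assert influence(PairState(100, 0.0, 0.0), p) == 0.0

    def test_point_symmetry(self, harness_params, rng):
        p = harness_params
        for _ in range(20):
            d = rng.uniform(1, 300)
            psi, dph = rng.uniform(-3, 3, 2)
            assert influence(PairState(d, psi, dph), p) == pytest.approx(
                influence(PairState(d, -psi, -dph), p))

    def test_top_k_by_exhaustive_ranking(self, harness_params, rng):
        p = harness_params
        n = 8
        xs = rng.uniform(-100, 100, n)
        ys = rng.uniform(-100, 100, n)
        phis = rng.uniform(-3, 3, n)
        got = select_neighbors(0, xs, ys, phis, p, k=2)
        # brute force
        infl = {}
        for j in range(1, n):
            dx, dy = xs[j] - xs[0], ys[j] - ys[0]
            s = PairState(math.hypot(dx, dy),
                          math.atan2(dy, dx) - phis[0],
                          phis[j] - phis[0])
            from burstcoast.core_model import wrap_angle
            s = PairState(s.d, wrap_angle(s.psi), wrap_angle(s.delta_phi))
            infl[j] = influence(s, p)
        expected = sorted(infl, key=lambda j: (-infl[j], j))[:2]
        assert list(got) == expected

    def test_single_neighbor_and_ties(self, harness_params):
        p = harness_params
        xs = np.array([0.0, 50.0])
        ys = np.array([0.0, 0.0])
        phis = np.array([0.0, 1.0])
        assert list(select_neighbors(0, xs, ys, phis, p)) == [1]
        # two neighbors in mirror positions: identical influence, lower id wins
        xs = np.array([0.0, 50.0, 50.0])
        ys = np.array([0.0, 30.0, -30.0])
        phis = np.array([0.0, 0.5, -0.5])
        got = select_neighbors(0, xs, ys, phis, p, k=1)
        assert list(got) == [1]


class TestAttemptHeading:
    def test_center_accept(self):
        assert attempt_heading(0, 0, 0.3, 0.1, 50, Arena(250), 2.0)

    def test_wallward_reject(self):
        # 1 mm off the wall heading radially outward with a 50 mm kick
        assert not attempt_heading(249.0, 0.0, 0.0, 0.0, 50, Arena(250), 2.0)

    def test_acceptance_region_matches_geometric_scan(self):
        arena, l_c, length = Arena(250), 2.0, 60.0
        x, y, phi = 180.0, 0.0, 0.0
        headings = np.linspace(-math.pi, math.pi, 10_000)
        for dphi in headings[:: 500]:
            ex = x + (length + l_c) * math.cos(phi + dphi)
            ey = y + (length + l_c) * math.sin(phi + dphi)
            expected = math.hypot(ex, ey) < arena.R
            assert attempt_heading(x, y, phi, dphi, length, arena,
                                   l_c) == expected


class TestRunSimulation:
    def test_containment(self, single_run):
        r = np.hypot(single_run.trajectory.x_mm, single_run.trajectory.y_mm)
        assert (r < 250.0).all()

    def test_determinism(self, params_single):
        cfg = SimulationRun(n_fish=2, duration=30.0, seed=77,
                            params=params_single)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        pd.testing.assert_frame_equal(a.trajectory, b.trajectory)
        pd.testing.assert_frame_equal(a.kicks, b.kicks)

    def test_speed_nonincreasing_within_kick(self, single_run, params_single):
        tr = single_run.trajectory
        x = tr.x_mm.to_numpy()
        y = tr.y_mm.to_numpy()
        step = np.hypot(np.diff(x), np.diff(y))
        # within a kick (no onset between frames) consecutive glide steps shrink
        kt = single_run.kicks.t_start.to_numpy()
        t = tr.time_s.to_numpy()[:-1]
        inside = np.array([not np.any((kt > t0) & (kt <= t0 + 0.08 + 1e-9))
                           for t0 in t[:-1]])
        shrink = step[1:] <= step[:-1] + 1e-9
        assert shrink[inside].mean() > 0.999

    def test_no_turning_forces_straight_lines(self, params_single):
        d = params_single.to_dict()
        d.update(gamma_w=1e-12, gamma_R=1e-12, alpha=0.5)
        from burstcoast.core_model import LightParams
        p = LightParams.from_dict(d)
        res = run_simulation(SimulationRun(n_fish=1, duration=60.0, seed=3,
                                           params=p))
        k = res.kicks
        # headings only change via the uniform fallback at the wall; between
        # fallbacks the heading is constant
        dphi = np.abs(k.dphi_random.to_numpy())
        assert ((dphi < 1e-9) | (dphi > 1e-3)).all()
        assert (np.abs(k.dphi_wall) < 1e-9).all()
        r = np.hypot(res.trajectory.x_mm, res.trajectory.y_mm)
        assert (r < 250.0).all()

    def test_event_engine_matches_dense_integration(self, single_run,
                                                    params_single):
        """Trajectory equals Simpson integration of the glide speed at 1 ms."""
        tau0 = params_single.tau0
        kicks = single_run.kicks
        tr = single_run.trajectory
        sel = kicks.iloc[10:20]
        for _, k in sel.iterrows():
            frames = tr[(tr.time_s >= k.t_start)
                        & (tr.time_s < k.t_start + k.tau_s)]
            dts = frames.time_s.to_numpy() - k.t_start
            t_grid = np.union1d(np.arange(0.0, k.tau_s, 1e-3), dts)
            v = speed_profile(k.length_mm, k.tau_s, tau0, t_grid)
            disp = cumulative_simpson(v, x=t_grid, initial=0.0)
            at_frames = disp[np.searchsorted(t_grid, dts)]
            xs = k.x0_mm + at_frames * math.cos(k.heading_rad)
            ys = k.y0_mm + at_frames * math.sin(k.heading_rad)
            assert np.max(np.abs(frames.x_mm.to_numpy() - xs)) < 1e-6
            assert np.max(np.abs(frames.y_mm.to_numpy() - ys)) < 1e-6

    def test_kick_independence(self, single_run):
        """Successive kick durations/lengths are uncorrelated."""
        k = single_run.kicks
        tau = k.tau_s.to_numpy()
        if len(tau) > 50:
            c = np.corrcoef(tau[:-1], tau[1:])[0, 1]
            assert abs(c) < 0.15

    def test_wallward_shift_with_longer_kicks(self, params_single):
        """Stochastic ordering: longer kicks concentrate the fish nearer
        the wall (social terms off, wall repulsion fixed)."""
        from burstcoast.core_model import LightParams
        means = {}
        for label, v_bar in [("short", 80.0), ("long", 240.0)]:
            d = params_single.to_dict()
            d.update(gamma_att=1e-12, gamma_ali=1e-12, v_bar=v_bar)
            p = LightParams.from_dict(d)
            res = run_simulation(SimulationRun(n_fish=1, duration=400.0,
                                               seed=5, params=p))
            r_w = 250.0 - np.hypot(res.trajectory.x_mm, res.trajectory.y_mm)
            means[label] = r_w.mean()
        assert means["long"] < means["short"]

    def test_trajectory_shape(self, group5_run):
        tr = group5_run.trajectory
        assert set(tr.columns) >= {"frame", "time_s", "fish_id", "x_mm",
                                   "y_mm", "heading_rad"}
        per_frame = tr.groupby("frame").size()
        assert (per_frame == 5).all()
        assert tr.frame.max() == int(120.0 / 0.04)
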