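import math

import numpy as np
import pytest

from locogear import (
    ArenaSpec,
    PipelineConfig,
    Trajectory,
    activity_profile,
    compute_endpoints,
    episode_curvature,
    incidence_second_gear,
    mean_dwell_time,
    mean_max_speed,
    mean_spatial_spread,
    run_pipeline,
    total_distance,
)
from locogear.segment import MotionEpisode
from locogear.synth import SynthConfig, generate_recording

from conftest import clean_trajectory, make_recording

SQ_ARENA = ArenaSpec(width_cm=320, height_cm=435)  # cm == px


def ep(vmax=5.0, gear=1, dwell=1.0, path=10.0, start=0, end=12, curv=None):
    return MotionEpisode(start=start, end=end, dwell_s=dwell, path_cm=path,
                         max_speed_cms=vmax, log_max_sd=float(np.log10(vmax)),
                         gear=gear, curvature_pct=curv)


class TestScalarEndpoints:
    def test_incidence(self):
        assert incidence_second_gear([ep(gear=g) for g in (1, 2, 1, 2)]) == 50.0
        assert incidence_second_gear([ep(gear=1)] * 3) == 0.0
        assert math.isnan(incidence_second_gear([]))

    def test_total_distance(self):
        assert total_distance([ep(path=100.0)]) == 1.0
        assert total_distance([]) == 0.0

    def test_mean_max_speed(self):
        eps = [ep(vmax=15, gear=2), ep(vmax=25, gear=2)]
        assert mean_max_speed(eps, 2) == 20.0
        assert mean_max_speed([ep(vmax=7)], 1) == 7.0
        assert math.isnan(mean_max_speed(eps, 1))

    def test_mean_dwell(self):
        assert mean_dwell_time([ep(dwell=25 / 12.8)], 1) == pytest.approx(1.953125)
        assert mean_dwell_time([ep(dwell=d) for d in (1, 2, 3)], 1) == 2.0

    def test_mean_spread(self):
        assert mean_spatial_spread([ep(path=10.0), ep(path=30.0)], 1) == 20.0
        assert mean_spatial_spread([ep(path=12.5)], 1) == 12.5


class TestCurvature:
    def test_straight_episode_is_zero(self, config):
        t = Trajectory(12.8, np.arange(13.0), np.zeros(13), np.ones(13, bool))
        c = episode_curvature(t, ep(start=0, end=12), SQ_ARENA, config)
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_corner_closed_form(self, config):
        # equal legs, corner at the window midpoint: ratio 2/sqrt(2)
        x = [0, 1, 2, 3, 3, 3, 3.0]
        y = [0, 0, 0, 0, 1, 2, 3.0]
        t = Trajectory(12.8, np.array(x), np.array(y), np.ones(7, bool))
        c = episode_curvature(t, ep(start=0, end=6), SQ_ARENA, config)
        assert c == pytest.approx((math.sqrt(2) - 1) * 100, abs=1e-9)

    def test_semicircle_matches_arc_chord_ratio(self):
        # dense sampling: one 0.5 s window spans a semicircular arc
        rate = 128.0
        config = PipelineConfig()
        w = int(round(0.5 * rate))
        ang = np.linspace(0.0, np.pi, w + 1)
        t = Trajectory(rate, 100 + 50 * np.cos(ang), 100 + 50 * np.sin(ang),
                       np.ones(w + 1, bool))
        c = episode_curvature(t, ep(start=0, end=w), SQ_ARENA, config)
        assert c == pytest.approx((np.pi / 2 - 1) * 100, rel=0.01)

    def test_short_episode_has_no_curvature(self, config):
        t = Trajectory(12.8, np.arange(5.0), np.zeros(5), np.ones(5, bool))
        assert math.isnan(episode_curvature(t, ep(start=0, end=4), SQ_ARENA, config))

    def test_degenerate_chord_skipped(self, config):
        # a closed loop within the window has ~zero chord; window is skipped
        ang = np.linspace(0, 2 * np.pi, 7)
        t = Trajectory(12.8, 50 + 5 * np.cos(ang), 50 + 5 * np.sin(ang), np.ones(7, bool))
        assert math.isnan(episode_curvature(t, ep(start=0, end=6), SQ_ARENA, config))

    def test_raw_ratio_mode(self, config):
        x = [0, 1, 2, 3, 3, 3, 3.0]
        y = [0, 0, 0, 0, 1, 2, 3.0]
        t = Trajectory(12.8, np.array(x), np.array(y), np.ones(7, bool))
        r = episode_curvature(t, ep(start=0, end=6), SQ_ARENA, config, as_ratio=True)
        assert r == pytest.approx(math.sqrt(2))

    def test_curvature_nonnegative_on_synthetic(self, arena, config):
        _, traj, _ = make_recording(13)
        res = run_pipeline(traj, arena, config, fit_mixture=False)
        vals = [e.curvature_pct for e in res.episodes if e.curvature_pct is not None]
        assert all(v >= 0 or math.isnan(v) for v in vals)


class TestEndpointSet:
    def test_matches_brute_force_on_hand_built_trajectory(self, config):
        # 200-sample trajectory with two hand-placed episodes, one per gear
        rng = np.random.default_rng(0)
        x = np.full(200, 50.0)
        y = np.full(200, 50.0)
        # gear-1 episode, samples 20..45: slow wavy walk (~0.5 cm/sample)
        for i in range(21, 46):
            a = 0.3 * math.sin(i)
            x[i] = x[i - 1] + 0.5 * math.cos(a)
            y[i] = y[i - 1] + 0.5 * math.sin(a)
        x[46:120] = x[45]
        y[46:120] = y[45]
        # gear-2 episode, samples 120..150: fast walk (~1.5 cm/sample)
        for i in range(121, 151):
            a = 0.15 * math.sin(0.5 * i)
            x[i] = x[i - 1] + 1.5 * math.cos(a)
            y[i] = y[i - 1] + 1.5 * math.sin(a)
        x[151:] = x[150]
        y[151:] = y[150]
        traj = Trajectory(12.8, x, y, np.ones(200, bool))

        eps = []
        for (s, e) in [(20, 45), (120, 150)]:
            path = float(np.hypot(np.diff(x[s:e + 1]), np.diff(y[s:e + 1])).sum())
            vmax = 0.5 * 12.8 if s == 20 else 1.5 * 12.8
            eps.append(MotionEpisode(start=s, end=e, dwell_s=(e - s + 1) / 12.8,
                                     path_cm=path, max_speed_cms=vmax,
                                     log_max_sd=float(np.log10(vmax)),
                                     gear=1 if s == 20 else 2))
        got = compute_endpoints(traj, eps, SQ_ARENA, config)

        # independent brute-force recomputation
        assert got.incidence2_pct == 100.0 * 1 / 2
        assert got.distance_m == pytest.approx((eps[0].path_cm + eps[1].path_cm) / 100)
        for g, e in ((1, eps[0]), (2, eps[1])):
            assert got.mean_max_speed_cms[g] == e.max_speed_cms
            assert got.mean_dwell_s[g] == e.dwell_s
            assert got.mean_spread_cm[g] == e.path_cm
            # brute-force curvature: consecutive 6-interval windows
            ratios = []
            for k in range((e.end - e.start) // 6):
                s0 = e.start + 6 * k
                e0 = s0 + 6
                p = sum(math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
                        for i in range(s0, e0))
                ch = math.hypot(x[e0] - x[s0], y[e0] - y[s0])
                if ch >= 0.1:
                    ratios.append(p / ch)
            expect = (np.mean(ratios) - 1) * 100
            assert got.mean_curvature_pct[g] == pytest.approx(expect, abs=1e-12)
            assert got.n_episodes[g] == 1

    def test_duplicating_episodes_keeps_means_doubles_distance(self, config):
        t = Trajectory(12.8, np.arange(60.0), np.zeros(60), np.ones(60, bool))
        eps = [ep(start=0, end=12, gear=1, vmax=6, dwell=1.0, path=12, curv=0.0),
               ep(start=20, end=40, gear=2, vmax=20, dwell=1.6, path=30, curv=0.0)]
        one = compute_endpoints(t, eps, SQ_ARENA, config)
        two = compute_endpoints(t, eps + eps, SQ_ARENA, config)
        assert two.distance_m == pytest.approx(2 * one.distance_m)
        assert two.incidence2_pct == one.incidence2_pct
        for g in (1, 2):
            assert two.mean_max_speed_cms[g] == one.mean_max_speed_cms[g]
            assert two.mean_dwell_s[g] == one.mean_dwell_s[g]
            assert two.mean_spread_cm[g] == one.mean_spread_cm[g]

    def test_empty_gear_reported_missing(self, config):
        t = Trajectory(12.8, np.arange(20.0), np.zeros(20), np.ones(20, bool))
        got = compute_endpoints(t, [ep(start=0, end=12, gear=1, curv=0.0)], SQ_ARENA, config)
        assert got.incidence2_pct == 0.0
        assert math.isnan(got.mean_max_speed_cms[2])
        assert got.n_episodes[2] == 0

    def test_unlabelled_episodes_rejected(self, config):
        t = Trajectory(12.8, np.arange(20.0), np.zeros(20), np.ones(20, bool))
        with pytest.raises(ValueError, match="gear-labelled"):
            compute_endpoints(t, [ep(gear=None)], SQ_ARENA, config)

    def test_means_lie_within_input_range(self, arena, config):
        _, traj, _ = make_recording(14)
        res = run_pipeline(traj, arena, config, fit_mixture=False)
        for g in (1, 2):
            vals = [e.max_speed_cms for e in res.episodes if e.gear == g]
            if vals:
                assert min(vals) <= res.endpoints.mean_max_speed_cms[g] <= max(vals)

    def test_distance_matches_ground_truth_paths(self, arena, config):
        _, _, truth = make_recording(15, clean=True)
        t = clean_trajectory(truth)
        res = run_pipeline(t, arena, config, fit_mixture=False)
        x, y = truth.clean_positions[:, 0] * arena.cm_per_px_x, \
            truth.clean_positions[:, 1] * arena.cm_per_px_y
        truth_m = sum(
            float(np.hypot(np.diff(x[e.start:e.end + 1]), np.diff(y[e.start:e.end + 1])).sum())
            for e in truth.episodes) / 100
        assert res.endpoints.distance_m == pytest.approx(truth_m, rel=0.02)

    def test_gear2_mean_speed_matches_lognormal_moment(self, arena, config):
        _, _, truth = make_recording(16, episode_rate=15.0, clean=True)
        t = clean_trajectory(truth)
        res = run_pipeline(t, arena, config, fit_mixture=False)
        # mean of 10**N(1.24, 0.10) = 10**(mu + sigma^2 ln10 / 2)
        expect = 10 ** (1.24 + 0.10**2 * np.log(10) / 2)
        assert res.endpoints.mean_max_speed_cms[2] == pytest.approx(expect, rel=0.07)


class TestActivityProfile:
    def test_empty_episode_list(self):
        bins, motion_s, phases = activity_profile([], 23040, 12.8)
        assert motion_s.sum() == 0.0
        assert phases == []

    def test_binned_time_conserves_episode_time(self):
        eps = [ep(start=100, end=180), ep(start=8000, end=8100)]
        _, motion_s, _ = activity_profile(eps, 23040, 12.8)
        total = sum((e.end - e.start + 1) / 12.8 for e in eps)
        assert motion_s.sum() == pytest.approx(total, abs=len(eps) / 12.8)

    def test_two_phase_circadian_pattern_detected(self):
        # active hour, quiet hour, active hour
        profile = (1.5, 0.03, 1.5) + (0.03,) * 21
        cfg = SynthConfig(duration_s=3 * 3600.0, episode_rate=8.0,
                          circadian_profile=profile, seed=30,
                          artifact_rates={"out_of_arena": 0, "corner_jump": 0, "teleport": 0})
        traj, truth = generate_recording(cfg)
        _, motion_s, phases = activity_profile(truth.episodes, len(traj), 12.8)
        truth_phases = [(0, 5), (12, 17)]  # 10-min bins of the active hours
        for ts, te in truth_phases:
            best = 0.0
            for s, e in phases:
                inter = max(0, min(e, te) - max(s, ts) + 1)
                union = (e - s + 1) + (te - ts + 1) - inter
                best = max(best, inter / union)
            assert best >= 0.5


class TestLesionPhenotype:
    def test_direction_of_change_pattern(self, arena, config):
        from locogear.synth import lesioned_config
        base = SynthConfig(duration_s=1800.0, episode_rate=12.0,
                           circadian_profile=(1.0,), seed=40)
        les = lesioned_config(base)
        rb = run_pipeline(generate_recording(base)[0], arena, config, fit_mixture=False).endpoints
        rl = run_pipeline(generate_recording(les)[0], arena, config, fit_mixture=False).endpoints
        assert rl.incidence2_pct < rb.incidence2_pct
        assert rl.mean_max_speed_cms[2] < rb.mean_max_speed_cms[2]
        assert rl.mean_dwell_s[2] > rb.mean_dwell_s[2]
        assert rl.mean_spread_cm[2] > rb.mean_spread_cm[2]
        assert rl.mean_curvature_pct[2] > rb.mean_curvature_pct[2]
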