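"""Linking and motion metrics: displacement, linearity, speed, MSD, VAC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rnatraffic as rt
from rnatraffic.core import Spot, Track
from rnatraffic.tracking import (
    compute_metrics,
    compute_msd,
    ensemble_msd,
    ensemble_vac,
    link_spots,
    mean_speed,
    path_length,
    track_displacement,
    track_linearity,
    velocity_autocorrelation,
)


def _track(xy, dt=1.0, track_id=0):
    xy = np.asarray(xy, float)
    return Track(track_id=track_id, frames=np.arange(len(xy)), xy=xy, frame_interval=dt)


class TestLinking:
    def test_single_chain_links_into_one_track(self):
        by_frame = [[Spot(x=0.1 * f, y=0.0, frame=f)] for f in range(20)]
        tracks = link_spots(by_frame, max_link_dist=0.5, frame_interval=0.15)
        assert len(tracks) == 1 and len(tracks[0]) == 20

    def test_parallel_tracks_recovered_without_switches(self):
        p = rt.MotionParams(diffusion_coefficient=0.05, frame_interval=0.15,
                            n_frames=30, localization_noise=0.0)
        gt, _ = rt.simulate_population(p, 10, seed=2)  # grid spacing >> link radius
        by_frame = [[] for _ in range(30)]
        for t in gt:
            for f, (x, y) in zip(t.frames, t.xy):
                by_frame[f].append(Spot(x=float(x), y=float(y), frame=int(f)))
        linked = link_spots(by_frame, max_link_dist=1.0, frame_interval=0.15)
        assert len(linked) == 10
        # every linked track matches one ground-truth track exactly
        gt_starts = {tuple(np.round(t.xy[0], 9)): t for t in gt}
        for lt in linked:
            src = gt_starts[tuple(np.round(lt.xy[0], 9))]
            assert np.allclose(lt.xy, src.xy)

    def test_gap_beyond_max_gap_splits_track(self):
        by_frame = [[Spot(x=0.05 * f, y=0.0, frame=f)] for f in range(10)]
        by_frame[4] = []
        by_frame[5] = []  # 2 missing frames, max_gap=1 cannot bridge
        tracks = link_spots(by_frame, max_link_dist=0.5, max_gap=1, frame_interval=1.0)
        assert len(tracks) == 2

    def test_gap_closing_interpolates_flagged_spots(self):
        by_frame = [[Spot(x=0.1 * f, y=0.0, frame=f)] for f in range(8)]
        by_frame[3] = []
        tracks = link_spots(by_frame, max_link_dist=0.5, max_gap=1, frame_interval=1.0)
        assert len(tracks) == 1
        t = tracks[0]
        assert t.interpolated.sum() == 1
        i = int(np.where(t.interpolated)[0][0])
        assert t.frames[i] == 3
        assert t.xy[i, 0] == pytest.approx(0.3)


class TestMetrics:
    def test_displacement_345_triangle(self):
        assert track_displacement(_track([(0, 0), (3, 4)])) == pytest.approx(5.0)

    def test_closed_loop_displacement_zero(self):
        t = _track([(0, 0), (1, 0), (1, 1), (0, 0)])
        assert track_displacement(t) == 0.0
        assert track_linearity(t) == 0.0

    def test_linearity_hand_computed_corner_path(self):
        t = _track([(0, 0), (1, 0), (1, 1)])
        assert track_linearity(t) == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_stationary_track_linearity_defined_zero(self):
        t = _track([(1, 1), (1, 1), (1, 1)])
        assert track_linearity(t) == 0.0
        assert mean_speed(t) == 0.0

    def test_directed_fixture_recovers_speed_and_displacement(self,
                                                              noiseless_directed_params):
        tr = rt.simulate_directed_track(noiseless_directed_params, heading=0.7, seed=0)
        assert mean_speed(tr) == pytest.approx(2.6)
        assert track_displacement(tr) == pytest.approx(2.6 * tr.duration)

    def test_localization_noise_inflates_mean_speed(self):
        base = rt.MotionParams(diffusion_coefficient=0.05, frame_interval=0.15,
                               n_frames=50, localization_noise=0.0)
        noisy = rt.MotionParams(diffusion_coefficient=0.05, frame_interval=0.15,
                                n_frames=50, localization_noise=0.05)
        vs0 = [mean_speed(rt.simulate_brownian_track(base, seed=s)) for s in range(200)]
        vs1 = [mean_speed(rt.simulate_brownian_track(noisy, seed=s)) for s in range(200)]
        assert np.mean(vs1) > np.mean(vs0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linearity_bounded_and_equals_ratio(self, seed):
        p = rt.MotionParams(diffusion_coefficient=0.1, frame_interval=0.15, n_frames=20)
        t = rt.simulate_brownian_track(p, seed=seed)
        lin = track_linearity(t)
        assert 0.0 <= lin <= 1.0 + 1e-9
        assert lin == pytest.approx(track_displacement(t) / path_length(t))

    def test_metrics_invariant_under_rigid_motion(self):
        p = rt.MotionParams(diffusion_coefficient=0.1, frame_interval=0.15, n_frames=30)
        t = rt.simulate_brownian_track(p, seed=7)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        t2 = _track(t.xy @ R.T + [12.0, -5.0], dt=0.15)
        for fn in (track_displacement, path_length, track_linearity):
            assert fn(t2) == pytest.approx(fn(t))
        assert np.allclose(compute_msd(t)[1], compute_msd(t2)[1])


class TestMSD:
    def test_constant_velocity_is_quadratic_exactly(self):
        v, dt = 1.3, 0.5
        t = _track([(v * dt * i, 0.0) for i in range(30)], dt=dt)
        lags, msd = compute_msd(t)
        assert np.allclose(msd, (v * lags) ** 2)

    def test_stationary_track_is_zero(self):
        t = _track([(2.0, 2.0)] * 10)
        assert np.allclose(compute_msd(t)[1], 0.0)

    def test_max_lag_window_equals_squared_displacement(self):
        p = rt.MotionParams(diffusion_coefficient=0.1, frame_interval=0.15, n_frames=40)
        t = rt.simulate_brownian_track(p, seed=3)
        _, msd = compute_msd(t)
        assert msd[-1] == pytest.approx(track_displacement(t) ** 2)

    def test_brownian_ensemble_matches_einstein_relation(self, brownian_ensemble):
        lags, msd = ensemble_msd(brownian_ensemble, max_lag=5)
        assert np.all(np.abs(msd[1:] / (4 * 0.1 * lags[1:]) - 1) < 0.10)


class TestVAC:
    def test_constant_velocity_fully_correlated(self):
        t = _track([(0.4 * i, 0.0) for i in range(20)], dt=0.2)
        _, vac = velocity_autocorrelation(t, max_lag=5)
        assert np.allclose(vac, 1.0)

    def test_alternating_steps_anticorrelate(self):
        xy = [((i % 2), 0.0) for i in range(12)]
        _, vac = velocity_autocorrelation(_track(xy), max_lag=2)
        assert vac[0] == pytest.approx(1.0)
        assert vac[1] == pytest.approx(-1.0)

    def test_stationary_track_defined_curve(self):
        _, vac = velocity_autocorrelation(_track([(0, 0)] * 8), max_lag=3)
        assert vac[0] == 1.0 and np.allclose(vac[1:], 0.0)

    def test_brownian_ensemble_decorrelates(self, brownian_ensemble):
        """Diffusive motion has ~zero velocity autocorrelation at lag >= 1."""
        _, vac = ensemble_vac(brownian_ensemble, max_lag=5)
        assert vac[0] == pytest.approx(1.0)
        assert np.all(np.abs(vac[1:]) < 0.05)


def test_compute_metrics_consistency():
    p = rt.MotionParams(diffusion_coefficient=0.1, frame_interval=0.15, n_frames=25)
    t = rt.simulate_brownian_track(p, seed=11)
    m = compute_metrics(t)
    assert m.displacement <= m.path_length
    assert m.msd[0] == 0.0 and m.vac[0] == pytest.approx(1.0)
    assert m.msd_at_max_lag == pytest.approx(m.displacement**2)
    assert m.mean_speed == pytest.approx(m.path_length / m.duration)
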