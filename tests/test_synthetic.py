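"""Simulator contracts: motion statistics, perturbations, geometry, rendering."""

import numpy as np
import pytest

import rnatraffic as rt
from rnatraffic.synthetic import Perturbation
from rnatraffic.tracking import ensemble_msd


class TestBrownian:
    def test_zero_diffusion_is_stationary(self):
        p = rt.MotionParams(diffusion_coefficient=0.0, frame_interval=0.15,
                            n_frames=50, localization_noise=0.0)
        tr = rt.simulate_brownian_track(p, origin=(2.0, 3.0), seed=1)
        assert np.allclose(tr.xy, [2.0, 3.0])
        assert rt.track_displacement(tr) == 0.0

    def test_ensemble_msd_matches_4dt(self, brownian_ensemble):
        """Time/ensemble-averaged MSD follows the 2D Einstein relation 4·D·τ."""
        lags, msd = ensemble_msd(brownian_ensemble, max_lag=5)
        expected = 4 * 0.1 * lags[1:]
        assert np.all(np.abs(msd[1:] / expected - 1) < 0.10)

    def test_same_seed_reproduces(self):
        p = rt.MotionParams()
        a = rt.simulate_brownian_track(p, seed=42)
        b = rt.simulate_brownian_track(p, seed=42)
        assert np.array_equal(a.xy, b.xy)

    def test_invalid_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            rt.MotionParams(frame_interval=0.0)


class TestDirected:
    def test_straight_run_geometry(self):
        p = rt.MotionParams(directed_speed=2.0, direction_jitter=0.0,
                            frame_interval=0.5, n_frames=21, localization_noise=0.0)
        tr = rt.simulate_directed_track(p, heading=0.0, seed=0)
        assert rt.track_displacement(tr) == pytest.approx(20.0)
        assert rt.track_linearity(tr) == pytest.approx(1.0)

    def test_step_length_at_motor_speed(self):
        p = rt.MotionParams(directed_speed=2.6, direction_jitter=0.0,
                            frame_interval=1 / 7.36, n_frames=10,
                            localization_noise=0.0)
        tr = rt.simulate_directed_track(p, heading=1.0, seed=0)
        steps = np.linalg.norm(np.diff(tr.xy, axis=0), axis=1)
        assert np.allclose(steps, 2.6 / 7.36)  # 0.3533 µm per frame

    def test_moderate_jitter_keeps_high_linearity(self):
        # frozen Monte-Carlo bound: >=95% of tracks stay above linearity 0.7
        p = rt.MotionParams(directed_speed=2.6, direction_jitter=0.1,
                            frame_interval=1 / 6.66, n_frames=100,
                            localization_noise=0.0)
        lins = [rt.track_linearity(rt.simulate_directed_track(p, seed=s))
                for s in range(300)]
        assert np.mean(np.asarray(lins) > 0.7) >= 0.95

    def test_zero_speed_rejected(self):
        p = rt.MotionParams(directed_speed=0.0)
        with pytest.raises(ValueError):
            rt.simulate_directed_track(p, seed=0)


class TestPopulation:
    def test_directed_count_rounds_fraction(self):
        p = rt.MotionParams(directed_fraction=0.05, n_frames=10)
        _, labels = rt.simulate_population(p, 1000, seed=0)
        assert labels.count("directed") == 50

    def test_nocodazole_abolishes_directed(self):
        p = rt.MotionParams(directed_fraction=0.5, n_frames=10)
        _, labels = rt.simulate_population(p, 200, Perturbation.NOCODAZOLE, seed=0)
        assert labels.count("directed") == 0

    @pytest.mark.parametrize("pert", [Perturbation.CYTOCHALASIN_D, Perturbation.DMSO])
    def test_actin_and_vehicle_controls_do_not_change_directed_count(self, pert):
        p = rt.MotionParams(directed_fraction=0.05, n_frames=10)
        _, ref = rt.simulate_population(p, 400, Perturbation.NONE, seed=3)
        _, lab = rt.simulate_population(p, 400, pert, seed=3)
        assert lab.count("directed") == ref.count("directed") == 20


class TestGeometry:
    def test_concentric_discs_when_regular(self):
        g = rt.make_cell_geometry(128, 128, 0.1, 0.3, irregularity=0.0, seed=0)
        cx, cy = g.nucleus_centroid
        assert cx == pytest.approx(63.5 * 0.1)
        assert cy == pytest.approx(63.5 * 0.1)

    def test_nucleus_strictly_inside_cell(self, geometry):
        assert not np.any(geometry.nucleus_mask & ~geometry.cell_mask)
        assert geometry.nucleus_mask.sum() < geometry.cell_mask.sum()

    def test_seeds_give_different_outlines(self):
        a = rt.make_cell_geometry(seed=1)
        b = rt.make_cell_geometry(seed=2)
        assert not np.array_equal(a.cell_mask, b.cell_mask)

    def test_nucleus_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            rt.make_cell_geometry(nucleus_radius_fraction=0.95)


class TestSpotPlacement:
    def test_centroid_pattern_is_degenerate(self, geometry):
        pos = rt.sample_spot_positions(geometry, "centroid", 100, seed=0)
        assert np.allclose(pos, geometry.nucleus_centroid)

    def test_uniform_density_is_flat(self, geometry):
        """Chi-square of per-pixel counts against the multinomial expectation."""
        n = 100_000
        pos = rt.sample_spot_positions(geometry, "uniform", n, seed=1)
        px = geometry.pixel_size
        cols = np.round(pos[:, 0] / px).astype(int)
        rows = np.round(pos[:, 1] / px).astype(int)
        counts = np.zeros(geometry.shape)
        np.add.at(counts, (rows, cols), 1)
        cyto = geometry.cytoplasm_mask
        assert counts[~cyto].sum() == 0  # all inside the cytoplasm
        k = cyto.sum()
        expected = n / k
        chi2 = ((counts[cyto] - expected) ** 2 / expected).sum()
        # chi-square with k-1 dof: mean k-1, sd sqrt(2(k-1)); allow 3 sd
        assert abs(chi2 - (k - 1)) < 3 * np.sqrt(2 * (k - 1))

    def test_peripheral_lies_farther_out_than_uniform(self, geometry):
        cx, cy = geometry.nucleus_centroid
        uni = rt.sample_spot_positions(geometry, "uniform", 3000, seed=5)
        per = rt.sample_spot_positions(geometry, "peripheral", 3000, seed=5)
        d = lambda p: np.hypot(p[:, 0] - cx, p[:, 1] - cy).mean()
        assert d(per) > d(uni)

    def test_positions_stay_in_cytoplasm(self, geometry):
        for pattern in ("uniform", "perinuclear", "peripheral"):
            pos = rt.sample_spot_positions(geometry, pattern, 500, seed=9)
            px = geometry.pixel_size
            rows = np.round(pos[:, 1] / px).astype(int)
            cols = np.round(pos[:, 0] / px).astype(int)
            assert geometry.cytoplasm_mask[rows, cols].all()


class TestRender:
    def test_empty_scene_is_flat_background(self):
        rp = rt.RenderParams(background_level=50.0, noise_sd=0.0)
        st = rt.render_stack([], render=rp, shape=(32, 32), n_frames=3)
        assert np.allclose(st.frames, 50.0)

    def test_static_emitter_sits_at_argmax_every_frame(self):
        rp = rt.RenderParams(single_molecule_intensity=(1000.0, 0.0),
                             background_level=10.0, noise_sd=0.0, seed=0)
        st = rt.render_stack([], static_spots=[((1.6, 2.4), 1)], render=rp,
                             shape=(48, 48), pixel_size=0.1, n_frames=4)
        for f in range(4):
            r, c = np.unravel_index(np.argmax(st.frames[f]), st.frames[f].shape)
            assert (r, c) == (24, 16)

    def test_multiplicity_scales_integrated_intensity(self):
        rp = rt.RenderParams(single_molecule_intensity=(1000.0, 0.0),
                             background_level=0.0, noise_sd=0.0, seed=0)
        st = rt.render_stack([], static_spots=[((2.0, 2.0), 1), ((6.0, 2.0), 6)],
                             render=rp, shape=(40, 80), pixel_size=0.1, n_frames=1)
        i1 = rt.measure_spot_intensity(st.frames[0], (2.0, 2.0), 0.45, 0.1)
        i6 = rt.measure_spot_intensity(st.frames[0], (6.0, 2.0), 0.45, 0.1)
        assert i6 / i1 == pytest.approx(6.0, rel=0.05)

    def test_total_signal_conserved(self):
        rp = rt.RenderParams(single_molecule_intensity=(800.0, 0.0),
                             background_level=25.0, noise_sd=0.0, seed=0)
        st = rt.render_stack([], static_spots=[((3.0, 3.0), 1), ((5.0, 4.0), 2)],
                             render=rp, shape=(80, 80), pixel_size=0.1, n_frames=1)
        excess = (st.frames[0] - 25.0).sum()
        assert excess == pytest.approx(800.0 + 1600.0, rel=0.02)

    def test_invalid_psf_rejected(self):
        with pytest.raises(ValueError):
            rt.RenderParams(psf_sigma=0.0)
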