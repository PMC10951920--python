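"""Synthetic trajectory and movie generator."""

import numpy as np
import pytest

import gliotrack as gt

DT = 0.03


def _config(**kw):
    base = dict(
        mixture=[(gt.MotionModel("brownian", D=0.01), 1.0)],
        geometry=gt.Geometry("sheet", radius=200.0),
        localization_sigma=0.0,
        bleach_prob=0.0,
        n_tracks=50,
        max_frames=50,
        seed=1,
    )
    base.update(kw)
    return gt.SimulationConfig(**base)


class TestSimulateTracks:
    def test_zero_motion_zero_noise_is_stationary(self):
        cfg = _config(mixture=[(gt.MotionModel("brownian", D=0.0), 1.0)])
        ts = gt.simulate_tracks(cfg)
        for t in ts:
            assert np.allclose(t.xy, t.xy[0])

    def test_deterministic_and_csv_byte_stable(self, tmp_path):
        a = gt.simulate_tracks(_config(seed=7))
        b = gt.simulate_tracks(_config(seed=7))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        gt.write_tracks_csv(a, pa)
        gt.write_tracks_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_single_step_msd_matches_closed_form(self, brownian_factory):
        # mean squared single-frame displacement of 2D Brownian motion = 4 D dt
        D = 0.01
        ts = brownian_factory(D, n_tracks=200, n_frames=100, seed=3)
        sq = np.concatenate([((t.xy[1:] - t.xy[:-1]) ** 2).sum(axis=1) for t in ts])
        assert sq.size >= 19000
        assert np.isclose(sq.mean(), 4 * D * DT, rtol=0.05)

    def test_ensemble_msd_includes_noise_floor(self, brownian_factory):
        # MSD(tau) = 4 D tau + 4 sigma_loc^2 for uncorrelated localization noise
        D, sig = 0.005, 0.02
        ts = brownian_factory(D, n_tracks=300, n_frames=80, sigma=sig, seed=5)
        for k in (1, 3):
            sq = np.concatenate([((t.xy[k:] - t.xy[:-k]) ** 2).sum(axis=1) for t in ts])
            expected = 4 * D * k * DT + 4 * sig**2
            assert np.isclose(sq.mean(), expected, rtol=0.05)

    def test_confined_msd_plateaus_below_corral_bound(self):
        r = 0.2
        cfg = _config(
            mixture=[(gt.MotionModel("confined", D=0.05, corral_radius=r), 1.0)],
            n_tracks=50,
            max_frames=400,
        )
        ts = gt.simulate_tracks(cfg)
        long_lag = []
        for t in ts:
            d = t.xy[200:] - t.xy[:-200]
            long_lag.append((d**2).sum(axis=1))
        plateau = np.concatenate(long_lag).mean()
        assert plateau <= 4 * r**2
        assert plateau > 0.2 * r**2  # particles do move inside the corral

    def test_directed_motion_advances_along_drift(self):
        v = (0.5, 0.0)
        cfg = _config(mixture=[(gt.MotionModel("directed", D=0.0, drift=v), 1.0)])
        ts = gt.simulate_tracks(cfg)
        for t in ts:
            steps = np.diff(t.xy, axis=0)
            assert np.allclose(steps[:, 0], 0.5 * DT, atol=1e-12)

    def test_track_lengths_bounded(self):
        cfg = _config(bleach_prob=0.1, n_tracks=300, max_frames=40)
        ts = gt.simulate_tracks(cfg)
        lengths = np.array([len(t) for t in ts])
        assert lengths.min() >= 2 and lengths.max() <= 40
        assert np.median(lengths) < 20  # memoryless bleaching at p=0.1

    def test_invalid_mixture_fractions_rejected(self):
        with pytest.raises(gt.ConfigError):
            _config(mixture=[(gt.MotionModel("brownian", D=0.01), 0.7)])


class TestStagePresets:
    def test_eol_has_no_fast_component(self):
        cfg = gt.stage_preset("eOL", seed=1)
        assert all(m.D < 0.05 for m, _ in cfg.mixture)
        assert all(np.hypot(*m.drift) < 0.5 for m, _ in cfg.mixture)

    def test_mol_contains_directed_and_fast(self):
        cfg = gt.stage_preset("mOL", seed=1)
        kinds = {m.kind for m, _ in cfg.mixture}
        assert "directed" in kinds and "confined" in kinds
        assert any(m.D >= 0.05 for m, _ in cfg.mixture)

    def test_opc_is_isotropic_brownian(self):
        cfg = gt.stage_preset("OPC", seed=1)
        assert {m.kind for m, _ in cfg.mixture} == {"brownian"}

    def test_preset_reproducible(self):
        a = gt.simulate_tracks(gt.stage_preset("OPC", n_tracks=30, seed=1))
        b = gt.simulate_tracks(gt.stage_preset("OPC", n_tracks=30, seed=1))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.xy, tb.xy) and np.array_equal(ta.frames, tb.frames)

    def test_unknown_stage_rejected(self):
        with pytest.raises(gt.ConfigError):
            gt.stage_preset("astrocyte")


class TestRenderMovie:
    def test_stationary_particle_brightest_at_truth(self):
        t = gt.Track("a", np.array([0, 1]), np.array([[1.0, 1.2], [1.0, 1.2]]))
        ts = gt.TrackSet([t], pixel_size=0.1)  # pixel (10, 12)
        stack = gt.render_movie(ts, gt.PSFModel(), (32, 32), noise=False)
        y, x = np.unravel_index(stack.data[0].argmax(), (32, 32))
        assert (x, y) == (10, 12)

    def test_empty_trackset_is_background(self):
        stack = gt.render_movie(gt.TrackSet([]), gt.PSFModel(background=100), (16, 16), noise=False)
        assert np.all(stack.data == 100)

    def test_zero_amplitude_indistinguishable_from_background(self):
        from scipy import stats as sps

        t = gt.Track("a", np.arange(5), np.tile([1.0, 1.0], (5, 1)))
        ts = gt.TrackSet([t], pixel_size=0.1)
        psf0 = gt.PSFModel(amplitude=0.0)
        with_spot = gt.render_movie(ts, psf0, (32, 32), seed=1)
        empty = gt.render_movie(gt.TrackSet([]), psf0, (32, 32), seed=2)
        res = sps.ks_2samp(with_spot.data.ravel(), empty.data[0].ravel())
        assert res.pvalue > 0.01

    def test_out_of_bounds_point_names_track(self):
        t = gt.Track("runaway", np.array([0, 1]), np.array([[0.5, 0.5], [50.0, 0.5]]))
        ts = gt.TrackSet([t], pixel_size=0.1)
        with pytest.raises(gt.ValidationError, match="runaway"):
            gt.render_movie(ts, gt.PSFModel(), (32, 32))


class TestStationaryStack:
    def test_zero_jitter_no_noise_frames_identical(self):
        stack, _ = gt.make_stationary_stack(5, 0.0, seed=2, noise=False)
        assert stack.n_frames == 20  # default calibration series length
        assert all(np.array_equal(stack.data[0], f) for f in stack.data)

    def test_returns_truth_for_every_particle(self):
        stack, truth = gt.make_stationary_stack(7, 10.0, n_frames=5, seed=3)
        assert truth.shape == (7, 2)
        assert stack.n_frames == 5
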