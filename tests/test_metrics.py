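"""MSD, diffusion coefficient, confinement, circularity, direction vectors."""

import math

import numpy as np
import pytest

import gliotrack as gt
from gliotrack.io import Track, TrackSet


def _track(points, frames=None, id="t"):
    xy = np.asarray(points, dtype=float)
    return Track(id, np.asarray(frames if frames is not None else range(len(xy))), xy)


class TestMsdCurve:
    def test_collinear_unit_steps_hand_values(self):
        t = _track([(0, 0), (1, 0), (2, 0), (3, 0)])
        c = gt.msd_curve(t, frame_interval=1.0)
        assert np.allclose(c.lags, [1, 2, 3])
        assert np.allclose(c.msd, [1.0, 4.0, 9.0])
        assert np.array_equal(c.n_pairs, [3, 2, 1])

    def test_stationary_track_zero(self):
        t = _track([(2, 2)] * 5)
        c = gt.msd_curve(t, 0.03)
        assert np.all(c.msd == 0)

    def test_gapped_track_pair_enumeration(self):
        # frames {0,1,3}: lag 1 from (0,1); lag 2 from (1,3); lag 3 from (0,3)
        t = _track([(0, 0), (1, 0), (3, 0)], frames=[0, 1, 3])
        c = gt.msd_curve(t, 1.0)
        assert np.allclose(c.lags, [1, 2, 3])
        assert np.array_equal(c.n_pairs, [1, 1, 1])
        assert np.allclose(c.msd, [1.0, 4.0, 9.0])

    def test_long_track_consistent_with_pairwise(self):
        # the per-lag path (long tracks) must agree with the pairwise path
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(0, 0.1, (450, 2)), axis=0)
        long = Track("l", np.arange(450), xy)
        short = Track("s", np.arange(390), xy[:390])
        cl = gt.msd_curve(long, 0.03)
        cs = gt.msd_curve(short, 0.03)
        k = 50
        assert np.allclose(cl.msd[:k], gt.msd_curve(Track("x", np.arange(450), xy), 0.03).msd[:k])
        # cross-check one lag by brute force
        lag = 7
        brute = np.mean(((xy[lag:] - xy[:-lag]) ** 2).sum(axis=1))
        assert np.isclose(cl.msd[lag - 1], brute)
        assert np.isclose(cs.msd[lag - 1], np.mean(((xy[lag:390] - xy[: 390 - lag]) ** 2).sum(axis=1)))


class TestDiffusionCoefficient:
    def test_hand_value_collinear(self):
        t = _track([(0, 0), (1, 0), (2, 0), (3, 0)])
        c = gt.msd_curve(t, 1.0)
        # mean of (1/4, 4/8, 9/12)
        assert np.isclose(gt.diffusion_coefficient(c), 0.5)

    def test_stationary_is_zero(self):
        c = gt.msd_curve(_track([(1, 1)] * 4), 0.03)
        assert gt.diffusion_coefficient(c) == 0.0

    def test_max_lag_cap(self):
        t = _track([(0, 0), (1, 0), (2, 0), (3, 0)])
        c = gt.msd_curve(t, 1.0)
        assert np.isclose(gt.diffusion_coefficient(c, max_lag=1.5), 0.25)

    def test_brownian_recovery_and_noise_bias(self, brownian_factory):
        for D in (1e-4, 1e-3, 1e-2):
            ts = brownian_factory(D, n_tracks=500, n_frames=100, seed=17)
            est = np.array(
                [gt.diffusion_coefficient(gt.msd_curve(t, 0.03), max_lag=0.3) for t in ts]
            )
            assert abs(np.median(est) - D) / D < 0.10
        noisy = brownian_factory(1e-3, n_tracks=500, n_frames=100, sigma=0.02, seed=17)
        est = np.array(
            [gt.diffusion_coefficient(gt.msd_curve(t, 0.03), max_lag=0.3) for t in noisy]
        )
        assert np.median(est) > 1e-3  # localization noise biases D upward


class TestDisplacements:
    @pytest.mark.parametrize(
        "pts,d_net,d_tot",
        [
            ([(0, 0), (1, 0), (0, 0)], 0.0, 2.0),
            ([(i, 0) for i in range(11)], 10.0, 10.0),
            ([(0, 0), (3, 0), (3, 4)], 5.0, 7.0),
        ],
    )
    def test_hand_values(self, pts, d_net, d_tot):
        dn, dt_, _ = gt.displacements(_track(pts), 0.03)
        assert np.isclose(dn, d_net) and np.isclose(dt_, d_tot)

    def test_duration_uses_frame_span(self):
        t = _track([(0, 0), (1, 0), (2, 0)], frames=[0, 1, 5])
        assert gt.displacements(t, 0.03)[2] == pytest.approx(0.15)


class TestConfinementRatio:
    def test_closed_loop_zero_in_every_mode(self):
        for mode in gt.CONFINEMENT_MODES:
            assert gt.confinement_ratio(0.0, 2.0, 0.06, mode) == 0.0

    def test_straight_track_hand_values(self):
        # 10 unit steps, dt=0.03 -> t_track = 0.3 s, d_net/d_tot = 1
        t = _track([(i, 0) for i in range(11)])
        dn, dt_, tt = gt.displacements(t, 0.03)
        assert gt.confinement_ratio(dn, dt_, tt, "as_printed") == pytest.approx(0.3)
        assert gt.confinement_ratio(dn, dt_, tt, "sqrt_duration") == pytest.approx(math.sqrt(0.3))
        assert gt.confinement_ratio(dn, dt_, tt, "plain") == pytest.approx(1.0)

    def test_as_printed_linear_in_frame_interval(self):
        t = _track([(i, 0) for i in range(11)])
        r1 = gt.confinement_ratio(*gt.displacements(t, 0.03), "as_printed")
        r2 = gt.confinement_ratio(*gt.displacements(t, 0.015), "as_printed")
        assert np.isclose(r1, 2 * r2)

    def test_stationary_defined_as_zero(self):
        assert gt.confinement_ratio(0.0, 0.0, 0.3) == 0.0

    def test_ordering_confined_below_brownian_below_directed(self):
        geo = gt.Geometry("sheet", radius=200.0)
        kinds = {
            "confined": gt.MotionModel("confined", D=0.01, corral_radius=0.1),
            "brownian": gt.MotionModel("brownian", D=0.01),
            "directed": gt.MotionModel("directed", D=0.001, drift=(0.5, 0.0)),
        }
        medians = {}
        groups = []
        for name, m in kinds.items():
            cfg = gt.SimulationConfig(
                mixture=[(m, 1.0)], geometry=geo, localization_sigma=0.0,
                bleach_prob=0.0, n_tracks=150, max_frames=60, seed=13,
            )
            vals = [
                gt.confinement_ratio(*gt.displacements(t, 0.03), "plain")
                for t in gt.simulate_tracks(cfg)
            ]
            medians[name] = np.median(vals)
            groups.append(vals)
        assert medians["confined"] < medians["brownian"] < medians["directed"]
        assert gt.kruskal_wallis(groups).p_value < 0.001


class TestZeroOrigin:
    def test_starts_at_origin_and_translation_invariant(self):
        t = _track([(5, 5), (6, 5), (6, 7)])
        z = gt.zero_origin(t)
        assert np.array_equal(z[0], [0, 0])
        shifted = _track([(15, -5), (16, -5), (16, -3)])
        assert np.allclose(gt.zero_origin(shifted), z)


class TestCircularity:
    def test_unit_square(self):
        assert gt.circularity(1.0, 4.0) == pytest.approx(math.pi / 4)

    def test_zero_area(self):
        assert gt.circularity(0.0, 1.0) == 0.0

    def test_disc_scale_invariant(self):
        for r in (0.1, 1.0, 42.0):
            assert gt.circularity(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)

    def test_zero_perimeter_is_error(self):
        with pytest.raises(ValueError):
            gt.circularity(1.0, 0.0)


class TestMotionProfile:
    def _ts_from_zeroed(self, clouds):
        """Each cloud becomes one track starting at (0,0)."""
        tracks = []
        for i, pts in enumerate(clouds):
            xy = np.vstack([[0.0, 0.0], np.asarray(pts, dtype=float)])
            tracks.append(Track(f"t{i}", np.arange(len(xy)), xy))
        return TrackSet(tracks, cell_id="c")

    def test_unit_square_corners(self):
        ts = self._ts_from_zeroed([[(1, 0), (1, 1), (0, 1)]])
        prof = gt.motion_profile(ts)
        assert prof.area == pytest.approx(1.0)
        assert prof.perimeter == pytest.approx(4.0)
        assert prof.r_circ == pytest.approx(4 * math.pi / 16)

    def test_fine_circle_is_one_at_two_decimals(self):
        ang = np.linspace(0, 2 * np.pi, 257)[:-1]
        ts = self._ts_from_zeroed([np.column_stack([np.cos(ang), np.sin(ang)])])
        prof = gt.motion_profile(ts)
        assert round(prof.r_circ, 2) == 1.00
        # closed form for the regular n-gon: (pi/n) / tan(pi/n)
        assert prof.r_circ == pytest.approx((math.pi / 256) / math.tan(math.pi / 256), rel=1e-9)

    def test_collinear_cloud_is_linear(self):
        ts = self._ts_from_zeroed([[(x, 0.0) for x in np.linspace(0.1, 1, 20)]])
        prof = gt.motion_profile(ts)
        assert prof.area == 0.0 and prof.r_circ == 0.0

    def test_isotropic_beats_drifted(self, brownian_factory):
        iso = brownian_factory(0.01, n_tracks=120, n_frames=40, seed=21)
        cfg = gt.SimulationConfig(
            mixture=[(gt.MotionModel("directed", D=0.001, drift=(1.0, 0.0)), 1.0)],
            geometry=gt.Geometry("sheet", radius=200.0),
            localization_sigma=0.0, bleach_prob=0.0, n_tracks=120,
            max_frames=40, seed=21,
        )
        drift = gt.simulate_tracks(cfg)
        assert gt.motion_profile(iso).r_circ > gt.motion_profile(drift).r_circ


class TestDirectionVectors:
    def test_all_drift_plus_x_in_sector_zero(self):
        tracks = [
            Track(f"t{i}", np.arange(3), np.array([[0, 0], [1, 0.01 * i], [2, 0.02 * i]]))
            for i in range(5)
        ]
        vd = gt.direction_vectors(TrackSet(tracks))
        assert vd.sector_mass[0] == 1.0

    def test_opposite_tracks_split_evenly(self):
        a = Track("a", np.arange(2), np.array([[0, 0], [1, 0]]))
        b = Track("b", np.arange(2), np.array([[0, 0], [-1, 0]]))
        vd = gt.direction_vectors(TrackSet([a, b]), n_sectors=8)
        assert vd.sector_mass[0] == 0.5 and vd.sector_mass[4] == 0.5

    def test_isotropic_population_near_uniform(self, brownian_factory):
        ts = brownian_factory(0.01, n_tracks=10000, n_frames=3, seed=2)
        vd = gt.direction_vectors(ts, n_sectors=8)
        assert vd.sector_mass.max() - vd.sector_mass.min() < 0.03

    def test_metrics_translation_invariant(self, brownian_factory):
        ts = brownian_factory(0.005, n_tracks=10, n_frames=20, seed=8)
        shifted = TrackSet(
            [Track(t.id, t.frames.copy(), t.xy + [13.0, -7.0]) for t in ts],
            frame_interval=ts.frame_interval,
        )
        for t, s in zip(ts, shifted):
            assert np.allclose(
                gt.msd_curve(t, 0.03).msd, gt.msd_curve(s, 0.03).msd
            )
            assert gt.displacements(t, 0.03) == pytest.approx(gt.displacements(s, 0.03))
        assert gt.motion_profile(ts).r_circ == pytest.approx(gt.motion_profile(shifted).r_circ)
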