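"""Optical-mapping maps: preprocessing, activation, APD80, conduction velocity."""

import numpy as np
import pytest

from cardioscar import optical as O
from cardioscar.synth.optical import (
    APTemplate,
    SyntheticOpticalSpec,
    disk_mask,
    generate_optical,
)


def _single_pixel_movie(trace, dt=1.0, cl=None):
    frames = np.asarray(trace, dtype=float)[:, None, None] * np.ones((1, 3, 3))
    cl = cl if cl is not None else len(trace) * dt
    return O.OpticalRecording(
        frames=frames,
        frame_interval=dt,
        pixel_size=0.5,
        stimulus_times=np.array([0.0]),
        cycle_length=cl,
    )


class TestPreprocess:
    def test_inverted_dye_polarity_corrected(self, plane_wave):
        beat, _ = O.segment_beats(plane_wave.recording, average_last=1)
        norm, valid = O.preprocess(beat)
        # after correction, the trace rises to its max shortly after onset
        i, j = 24, 24
        assert valid[i, j]
        assert np.nanmax(norm[:, i, j]) == pytest.approx(1.0)
        up = np.argmax(norm[:, i, j] > 0.9)
        down = np.argmax(norm[::-1, i, j] > 0.9)
        assert up < len(norm) - down  # peak sits early (depolarization up)

    def test_constant_pixel_invalidated(self):
        tr = np.zeros(100)
        rec = _single_pixel_movie(tr)
        beat, _ = O.segment_beats(rec)
        norm, valid = O.preprocess(beat)
        assert not valid.any()

    def test_noiseless_peak_is_exactly_one(self, plane_wave):
        beat, _ = O.segment_beats(plane_wave.recording)
        norm, valid = O.preprocess(beat)
        assert np.nanmax(norm[:, valid]) == pytest.approx(1.0, abs=1e-12)


class TestSegmentBeats:
    def test_window_count(self):
        frames = np.zeros((2000, 2, 2))
        frames[::600] = 1.0
        rec = O.OpticalRecording(frames, 1.0, 0.5, np.array([0.0, 600.0, 1200.0]), 600.0)
        with pytest.warns(UserWarning, match="incomplete"):
            _, n = O.segment_beats(
                O.OpticalRecording(
                    frames, 1.0, 0.5, np.array([0.0, 600.0, 1200.0, 1800.0]), 600.0
                )
            )
        assert n == 3
        _, n2 = O.segment_beats(rec)
        assert n2 == 3

    def test_beat_average_idempotent_on_identical_beats(self, plane_wave):
        one, _ = O.segment_beats(plane_wave.recording, average_last=1)
        avg, _ = O.segment_beats(plane_wave.recording, average_last=3)
        np.testing.assert_allclose(one, avg, atol=1e-4)

    def test_no_complete_window_rejected(self):
        rec = _single_pixel_movie(np.zeros(100), dt=1.0, cl=100.0)
        rec.stimulus_times = np.array([50.0])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                O.segment_beats(rec)


class TestActivation:
    def test_smooth_upstroke_midpoint(self):
        """A sine-shaped upstroke has its steepest slope at the midpoint."""
        t = np.arange(200.0)
        tr = np.zeros_like(t)
        rise = (t >= 50) & (t <= 70)
        tr[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - 50) / 20))
        tr[t > 70] = 1.0
        norm = tr[:, None, None] * np.ones((1, 2, 2))
        act = O.detect_activation(norm, np.ones((2, 2), bool), 1.0, 0.5)
        assert act.valid.all()
        assert act.times[0, 0] == pytest.approx(60.0, abs=0.5)

    def test_equal_derivative_maxima_take_earliest(self):
        # binary-exact steps give two identical derivative maxima (k=1, k=3);
        # the earlier one is chosen, symmetric neighbors leave it unshifted
        tr = np.array([0.0, 0.125, 0.375, 0.5, 0.75, 0.875, 0.875, 0.875])
        norm = tr[:, None, None] * np.ones((1, 1, 1))
        act = O.detect_activation(norm, np.ones((1, 1), bool), 1.0, 0.5)
        assert act.valid[0, 0]
        assert act.times[0, 0] == pytest.approx(1.5)

    def test_edge_maximum_invalidated(self):
        tr = np.concatenate([[0.0, 1.0], np.full(48, 1.0)])  # jump at frame 0
        norm = tr[:, None, None] * np.ones((1, 1, 1))
        act = O.detect_activation(norm, np.ones((1, 1), bool), 1.0, 0.5)
        assert not act.valid[0, 0]

    def test_construction_oracle_on_plane_wave(self, plane_wave):
        out = O.analyze_recording(
            plane_wave.recording, spatial_sigma_px=0.0, temporal_window_frames=1
        )
        act = out["activation"]
        tt = plane_wave.truth.travel_time_ms
        err = np.abs(act.times - tt)[act.valid]
        assert np.max(err) <= plane_wave.recording.frame_interval / 2


class TestAPD80:
    def test_triangular_ap_closed_form(self):
        """Rise to 1 then linear fall to 0 over 100 ms: 20 % crossing at 80 ms."""
        t = np.arange(140.0)
        tr = np.zeros_like(t)
        tr[(t >= 19) & (t < 20)] = 0.5
        tr[t >= 20] = np.clip(1 - (t[t >= 20] - 20) / 100, 0, 1)
        norm = tr[:, None, None] * np.ones((1, 2, 2))
        act = O.detect_activation(norm, np.ones((2, 2), bool), 1.0, 0.5)
        apd = O.compute_apd80(norm, act)
        assert apd.valid.all()
        assert apd.apd80[0, 0] == pytest.approx(80.0, abs=1.0)

    def test_template_apd_recovered_within_one_frame(self):
        spec = SyntheticOpticalSpec(
            grid_shape=(16, 16),
            pixel_size=0.5,
            frame_interval=2.0,
            n_beats=2,
            ap_template=APTemplate(apd80_ms=150.0),
            noise_sd=0.0,
            seed=2,
        )
        res = generate_optical(spec)
        out = O.analyze_recording(
            res.recording, spatial_sigma_px=0.0, temporal_window_frames=1
        )
        apd = out["apd"]
        err = np.abs(apd.apd80[apd.valid] - 150.0)
        assert np.max(err) <= spec.frame_interval

    def test_no_repolarization_invalidated(self):
        t = np.arange(100.0)
        tr = np.clip((t - 10) / 2, 0, 1)  # rises, never repolarizes
        norm = tr[:, None, None] * np.ones((1, 1, 1))
        act = O.detect_activation(norm, np.ones((1, 1), bool), 1.0, 0.5)
        apd = O.compute_apd80(norm, act)
        assert not apd.valid[0, 0]


class TestIsochronesAndCV:
    def test_plane_wave_closed_form(self):
        h = w = 32
        x = np.arange(w) * 0.5  # mm
        times = np.tile(x / 0.5, (h, 1))  # T = x / (0.5 mm/ms) -> 50 cm/s
        act = O.ActivationMap(times, np.ones((h, w), bool), 1.0, 0.5)
        cv = O.estimate_cv(act)
        sel = cv.valid.copy()
        sel[:2] = sel[-2:] = False
        sel[:, :2] = sel[:, -2:] = False
        assert np.allclose(cv.speed[sel], 50.0, rtol=1e-9)
        assert np.allclose(cv.direction[sel][:, 0], 1.0, atol=1e-9)
        assert np.allclose(cv.direction[sel][:, 1], 0.0, atol=1e-9)

    def test_radial_wave_speed(self):
        h = w = 41
        px = 0.5
        yy, xx = np.mgrid[0:h, 0:w] * px
        r = np.hypot(xx - 10.0, yy - 10.0)
        times = r / 0.5  # 50 cm/s radial wave
        act = O.ActivationMap(times, np.ones((h, w), bool), 1.0, px)
        cv = O.estimate_cv(act)
        far = (r > 3.0) & cv.valid
        far[:3] = far[-3:] = False
        far[:, :3] = far[:, -3:] = False
        assert np.median(np.abs(cv.speed[far] - 50.0)) / 50.0 < 0.02

    def test_isochrone_geometry(self):
        h = w = 32
        x = np.arange(w) * 0.5
        times = np.tile(x / 0.5, (h, 1))
        act = O.ActivationMap(times, np.ones((h, w), bool), 1.0, 0.5)
        iso = O.build_isochrones(act, 5.0)
        assert len(iso) >= 4
        for _, contours in iso:
            for c in contours:
                # vertical lines: constant column coordinate
                assert np.ptp(c[:, 1]) < 1e-6
        # a step larger than the range yields at most one contour
        assert len(O.build_isochrones(act, 1e6)) <= 1

    def test_ht_patch_speed_ratio_recovered(self, ht_patch_movie):
        res = ht_patch_movie
        rois = res.truth.rois(3)
        out = O.analyze_recording(res.recording, rois=rois)
        cv = out["cv"]
        ht_speed = np.median(cv.speed[rois.ht & cv.valid])
        assert ht_speed == pytest.approx(0.55 * 50.0, rel=0.05)

    def test_insufficient_neighbors_invalidated(self):
        times = np.full((8, 8), np.nan)
        times[4, 4] = 10.0
        act = O.ActivationMap(times, np.isfinite(times), 1.0, 0.5)
        cv = O.estimate_cv(act)
        assert not cv.valid.any()


class TestRegionalDifference:
    def test_formula(self):
        speed = np.zeros((10, 10))
        speed[:5] = 50.0  # HM rows
        speed[5:] = 40.0  # HT rows
        rois = O.ROISet(hm=np.arange(100).reshape(10, 10) < 50,
                        ht=np.arange(100).reshape(10, 10) >= 50)
        d = O.regional_relative_difference(speed, np.ones((10, 10), bool), rois)
        assert d == pytest.approx(-20.0)

    def test_identical_rois_give_zero(self):
        vals = np.tile(np.linspace(1, 2, 10), (10, 1))
        hm = np.zeros((10, 10), bool)
        ht = np.zeros((10, 10), bool)
        hm[:5] = True
        ht[5:] = True
        assert O.regional_relative_difference(vals, np.ones((10, 10), bool),
                                              O.ROISet(hm, ht)) == pytest.approx(0.0)

    def test_small_roi_rejected(self):
        vals = np.ones((10, 10))
        hm = np.zeros((10, 10), bool)
        ht = np.zeros((10, 10), bool)
        hm[0, :5] = True
        ht[1, :] = True
        with pytest.raises(ValueError):
            O.regional_relative_difference(vals, np.ones((10, 10), bool),
                                           O.ROISet(hm, ht))


class TestEquivariances:
    def test_time_shift_leaves_maps_unchanged(self):
        common = dict(
            grid_shape=(24, 24), pixel_size=0.5, frame_interval=1.0, n_beats=2,
            hm_velocity_cm_s=40.0, noise_sd=0.0, seed=9,
        )
        a = generate_optical(SyntheticOpticalSpec(first_stimulus_ms=5.0, **common))
        b = generate_optical(SyntheticOpticalSpec(first_stimulus_ms=65.0, **common))
        oa = O.analyze_recording(a.recording, spatial_sigma_px=0, temporal_window_frames=1)
        ob = O.analyze_recording(b.recording, spatial_sigma_px=0, temporal_window_frames=1)
        np.testing.assert_allclose(oa["activation"].times, ob["activation"].times, atol=1e-6)
        np.testing.assert_allclose(oa["apd"].apd80, ob["apd"].apd80, atol=1e-6)
        np.testing.assert_allclose(oa["cv"].speed, ob["cv"].speed, rtol=1e-6)

    def test_pixel_size_doubles_speed(self):
        times = np.tile(np.arange(24.0), (24, 1))
        act1 = O.ActivationMap(times, np.ones((24, 24), bool), 1.0, 0.5)
        act2 = O.ActivationMap(times, np.ones((24, 24), bool), 1.0, 1.0)
        cv1 = O.estimate_cv(act1)
        cv2 = O.estimate_cv(act2)
        sel = cv1.valid & cv2.valid
        np.testing.assert_allclose(cv2.speed[sel], 2 * cv1.speed[sel], rtol=1e-9)


class TestSyntheticGenerator:
    def test_determinism(self):
        spec = SyntheticOpticalSpec(grid_shape=(16, 16), n_beats=2, noise_sd=30.0, seed=7)
        a = generate_optical(spec)
        b = generate_optical(spec)
        np.testing.assert_array_equal(a.recording.frames, b.recording.frames)

    def test_plane_wave_kinematics(self, plane_wave):
        """Travel time at distance d is d / v for the uniform medium."""
        tt = plane_wave.truth.travel_time_ms
        x_mm = np.arange(48) * 0.5
        expect = x_mm / 0.5  # 50 cm/s = 0.5 mm/ms
        np.testing.assert_allclose(tt[10], expect, atol=1e-9)

    def test_ht_ground_truth_speed_is_scaled(self, ht_patch_movie):
        truth = ht_patch_movie.truth
        assert np.all(truth.cv.speed[truth.ht_mask] == pytest.approx(27.5))

    def test_patch_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            disk_mask((32, 32), (30.0, 16.0), 5.0)
        bad = SyntheticOpticalSpec(grid_shape=(16, 16), ht_mask=np.ones((8, 8), bool))
        with pytest.raises(ValueError, match="mask"):
            generate_optical(bad)

    def test_noise_monotonically_degrades_recovery(self):
        """More sensor noise never improves CV/APD recovery (same seed)."""
        cv_err, apd_err = [], []
        for noise in (0.0, 60.0, 200.0):
            spec = SyntheticOpticalSpec(
                grid_shape=(32, 32), pixel_size=0.5, frame_interval=2.0,
                n_beats=2, noise_sd=noise, seed=13,
            )
            res = generate_optical(spec)
            out = O.analyze_recording(res.recording)
            cv, apd = out["cv"], out["apd"]
            sel = cv.valid & apd.valid
            sel[:4] = sel[-4:] = False
            sel[:, :4] = sel[:, -4:] = False
            cv_err.append(np.sqrt(np.mean((cv.speed[sel] - 50.0) ** 2)))
            apd_err.append(
                np.sqrt(np.mean((apd.apd80[sel] - spec.ap_template.apd80_ms) ** 2))
            )
        assert cv_err == sorted(cv_err)
        assert apd_err == sorted(apd_err)
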