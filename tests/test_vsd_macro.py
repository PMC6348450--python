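"""Wide-field VSD pipeline: arithmetic identities, threshold semantics,
landmark alignment and parameter recovery on synthetic movies."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cortiplast import synthetic_data as syn
from cortiplast import vsd_macro
from cortiplast.core_io import Config, ImageStack
from cortiplast.vsd_macro import (
    DffMovie,
    ResponseMap,
    align_and_superimpose,
    compute_dff_movie,
    detect_significant_pixels,
    find_initial_response,
    peak_area,
    roi_metrics,
)


def _stack(frames, onset=4):
    return ImageStack(np.asarray(frames, dtype=float), 4.0, (38.7, 34.8),
                      stim_onset_frame=onset)


def _movie(dff, baseline_sd, onset=4):
    return DffMovie(np.asarray(dff, dtype=float),
                    np.asarray(baseline_sd, dtype=float), onset, 4.0,
                    (4800 / 124, 6400 / 184))


class TestComputeDff:
    def test_identical_stim_and_blank_give_zero(self, rng):
        frames = rng.normal(1000, 20, size=(12, 16, 16))
        stim = [_stack(frames)]
        blank = [_stack(frames.copy())]
        movie = compute_dff_movie(stim, blank)
        assert np.abs(movie.dff).max() < 1e-12

    def test_fluorescence_doubling_gives_dff_one(self):
        # stim doubles from F0 to 2F0 at stimulus onset, blank stays at F0:
        # after subtraction and division by the baseline F0, dF/F = 1
        f0 = 500.0
        frames = np.full((10, 12, 12), f0)
        frames[4:] = 2 * f0
        movie = compute_dff_movie([_stack(frames)],
                                  [_stack(np.full((10, 12, 12), f0))])
        np.testing.assert_allclose(movie.dff[4:], 1.0, rtol=1e-12)
        np.testing.assert_allclose(movie.dff[:4], 0.0, atol=1e-12)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            compute_dff_movie([_stack(np.ones((8, 10, 10)))],
                              [_stack(np.ones((8, 12, 12)))])

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_dff_movie([_stack(np.ones((8, 6, 6)), onset=0)],
                              [_stack(np.ones((8, 6, 6)), onset=0)])

    def test_planted_peak_recovered_within_ten_percent(self):
        truth = syn.VsdGroundTruth()
        stim, blank, _ = syn.generate_vsd_trial_set(truth, 16, seed=7)
        movie = compute_dff_movie(stim, blank)
        masks = detect_significant_pixels(movie)
        frame, center = find_initial_response(masks, movie)
        met = roi_metrics(movie, center)
        assert met.defined
        assert met.peak_amplitude == pytest.approx(truth.peak_dff, rel=0.10)


class TestSignificance:
    def test_threshold_definition(self):
        dff = np.zeros((6, 4, 4))
        dff[3, 1, 1] = 8.0   # 8 x SD -> flagged
        dff[3, 2, 2] = 6.0   # 6 x SD -> not flagged
        movie = _movie(dff, np.ones((4, 4)), onset=2)
        masks = detect_significant_pixels(movie, sd_factor=7)
        assert masks.masks[3, 1, 1]
        assert not masks.masks[3, 2, 2]

    def test_infinite_factor_empties_masks(self):
        movie = _movie(np.ones((5, 3, 3)), np.ones((3, 3)), onset=1)
        assert not detect_significant_pixels(movie, sd_factor=np.inf).masks.any()

    def test_non_positive_factor_rejected(self):
        movie = _movie(np.ones((5, 3, 3)), np.ones((3, 3)), onset=1)
        with pytest.raises(ValueError):
            detect_significant_pixels(movie, sd_factor=0)

    @given(st.floats(1.0, 20.0), st.floats(0.0, 10.0))
    def test_mask_count_non_increasing_in_sd_factor(self, f1, delta):
        rng = np.random.default_rng(99)
        dff = rng.normal(0, 1, size=(8, 6, 6))
        movie = _movie(dff, np.full((6, 6), 0.3), onset=2)
        n1 = detect_significant_pixels(movie, sd_factor=f1).masks.sum()
        n2 = detect_significant_pixels(movie, sd_factor=f1 + delta).masks.sum()
        assert n2 <= n1

    def test_noiseless_crossing_matches_closed_form(self):
        # threshold crossing of the known generator waveform: flagged frames
        # are exactly those where the model value exceeds 7 sigma
        truth = syn.VsdGroundTruth(noise_sd=1.0)  # any; only model used
        model = syn.vsd_response_movie(truth)
        sigma = 0.01
        movie = _movie(model, np.full(truth.field_px, sigma),
                       onset=truth.stim_onset_frame)
        masks = detect_significant_pixels(movie, sd_factor=7)
        np.testing.assert_array_equal(masks.masks, model > 7 * sigma)


class TestInitialResponse:
    def test_single_pixel(self):
        m = np.zeros((8, 5, 5), dtype=bool)
        m[5, 2, 3] = True
        masks = vsd_macro.SignificanceMasks(m, 7.0)
        frame, center = find_initial_response(masks)
        assert frame == 5 and center == (2.0, 3.0)

    def test_region_polygon_selects_designated_blob(self):
        # two simultaneous blobs; the region polygon picks one of them
        m = np.zeros((6, 10, 20), dtype=bool)
        m[2, 2:4, 2:4] = True     # blob A (outside region)
        m[2, 6:8, 14:16] = True   # blob B (inside region)
        masks = vsd_macro.SignificanceMasks(m, 7.0)
        poly = np.array([[5, 12], [5, 18], [9, 18], [9, 12]])
        frame, center = find_initial_response(masks, region_polygon=poly)
        assert frame == 2
        assert center == (6.5, 14.5)

    def test_all_false_returns_no_response(self):
        masks = vsd_macro.SignificanceMasks(np.zeros((4, 3, 3), dtype=bool), 7.0)
        assert find_initial_response(masks) is None


class TestRoiMetrics:
    def test_ramp_latency_and_time_to_peak(self, rng):
        # baseline noise, threshold crossing at frame 4 (16 ms), peak at
        # frame 12 (48 ms) after stimulus
        n, h, w = 20, 9, 9
        onset = 4
        trace = np.zeros(n)
        # ramp from frames +4 to +12 post-stimulus, suprathreshold from +4 on
        trace[onset + 4:onset + 13] = np.linspace(0.1, 1.0, 9)
        trace[onset + 13:] = 1.0
        dff = np.tile(trace[:, None, None], (1, h, w))
        dff[:onset] = rng.normal(0, 1e-3, size=(onset, h, w))
        movie = _movie(dff, np.full((h, w), 1e-3), onset=onset)
        met = roi_metrics(movie, (4, 4), roi_radius_px=2)
        assert met.defined
        assert met.latency_ms == pytest.approx(16.0)
        assert met.time_to_peak_ms == pytest.approx(48.0)

    def test_all_zero_trace_flagged_undefined(self):
        movie = _movie(np.zeros((10, 6, 6)), np.zeros((6, 6)), onset=3)
        met = roi_metrics(movie, (3, 3))
        assert not met.defined and met.peak_amplitude is None

    def test_latency_not_after_time_to_peak(self):
        truth = syn.VsdGroundTruth(peak_dff=0.196, onset_latency_ms=16.0)
        stim, blank, _ = syn.generate_vsd_trial_set(truth, 8, seed=3)
        movie = compute_dff_movie(stim, blank)
        masks = detect_significant_pixels(movie)
        _, center = find_initial_response(masks, movie)
        met = roi_metrics(movie, center)
        assert met.defined
        assert met.latency_ms <= met.time_to_peak_ms

    def test_bad_radius_rejected(self):
        movie = _movie(np.zeros((6, 4, 4)), np.ones((4, 4)), onset=2)
        with pytest.raises(ValueError):
            roi_metrics(movie, (2, 2), roi_radius_px=0)


class TestPeakArea:
    def _metrics(self, frame):
        return vsd_macro.RoiMetrics(defined=True, peak_amplitude=1.0,
                                    latency_ms=0.0, time_to_peak_ms=0.0,
                                    peak_frame=frame)

    def test_area_from_sensor_geometry(self):
        # 1000 pixels x (6.4/184) x (4.8/124) mm^2 ~ 1.347 mm^2
        h, w = 124, 184
        m = np.zeros((3, h, w), dtype=bool)
        m[1].flat[:1000] = True
        movie = _movie(np.zeros((3, h, w)), np.ones((h, w)), onset=1)
        rm = peak_area(movie, vsd_macro.SignificanceMasks(m, 7.0), self._metrics(1))
        assert rm.area_mm2 == pytest.approx(1000 * (6.4 / 184) * (4.8 / 124),
                                            rel=1e-9)
        assert rm.area_mm2 == pytest.approx(1.347, abs=5e-3)

    def test_empty_and_full_masks(self):
        h, w = 124, 184
        movie = _movie(np.zeros((2, h, w)), np.ones((h, w)), onset=1)
        empty = vsd_macro.SignificanceMasks(np.zeros((2, h, w), dtype=bool), 7.0)
        assert peak_area(movie, empty, self._metrics(1)).area_mm2 == 0.0
        full = vsd_macro.SignificanceMasks(np.ones((2, h, w), dtype=bool), 7.0)
        assert peak_area(movie, full, self._metrics(1)).area_mm2 == \
            pytest.approx(6.4 * 4.8)

    def test_undefined_peak_gives_zero_area(self):
        movie = _movie(np.zeros((2, 6, 6)), np.ones((6, 6)), onset=1)
        masks = vsd_macro.SignificanceMasks(np.ones((2, 6, 6), dtype=bool), 7.0)
        rm = peak_area(movie, masks, vsd_macro.RoiMetrics(defined=False))
        assert rm.area_mm2 == 0.0 and not rm.mask.any()


def _square_map(offset=(0, 0), angle_pts=((50, 10), (50, 70))):
    mask = np.zeros((80, 80), dtype=bool)
    r, c = 20 + offset[0], 30 + offset[1]
    mask[r:r + 12, c:c + 12] = True
    mca = (40 + offset[0], 40 + offset[1])
    fissure = tuple((p[0] + offset[0], p[1] + offset[1]) for p in angle_pts)
    return ResponseMap(mask, float(mask.sum()), (38.7, 34.8),
                       {"mca": mca, "fissure": fissure})


class TestAlignment:
    def test_identical_prealigned_maps(self):
        maps = [_square_map() for _ in range(4)]
        out = align_and_superimpose(maps)
        assert out.overlap.max() == 4
        np.testing.assert_array_equal(out.overlap == 4, maps[0].mask)
        # 50% contour threshold = ceil(4/2) = 2 -> equals the common mask
        np.testing.assert_array_equal(out.contour_mask, maps[0].mask)

    def test_two_disjoint_maps_contour_is_union(self):
        a = _square_map()
        b = _square_map()
        b.mask = np.roll(a.mask, 30, axis=0)  # same landmarks, moved blob
        out = align_and_superimpose([a, b])
        assert out.threshold == 1
        np.testing.assert_array_equal(out.contour_mask, a.mask | b.mask)

    def test_translation_restored_by_landmarks(self):
        # rigid-motion oracle: a map translated together with its landmarks
        # realigns exactly onto the reference
        a = _square_map()
        b = _square_map(offset=(7, -5))
        out = align_and_superimpose([a, b])
        assert (out.overlap == 2).sum() == a.mask.sum()
        np.testing.assert_array_equal(out.overlap == 2, a.mask)

    def test_rotation_restored_by_landmarks(self):
        a = _square_map()
        b = _square_map(angle_pts=((50, 10), (10, 50)))  # fissure rotated 45 deg
        from skimage.transform import EuclideanTransform, warp
        theta = -np.pi / 4
        rot = EuclideanTransform(rotation=theta)
        shift = np.array([40, 40])[::-1] - rot(np.array([40, 40])[::-1][None])[0]
        tf = EuclideanTransform(rotation=theta, translation=shift)
        b.mask = warp(a.mask.astype(float), inverse_map=tf.inverse, order=0) > 0.5
        out = align_and_superimpose([a, b])
        overlap_frac = (out.overlap == 2).sum() / a.mask.sum()
        assert overlap_frac > 0.9  # rasterisation nibbles the square's edge

    def test_map_without_landmarks_excluded_with_warning(self):
        a = _square_map()
        bad = ResponseMap(a.mask.copy(), 1.0, (38.7, 34.8), {})
        with pytest.warns(UserWarning, match="landmark"):
            out = align_and_superimpose([a, bad])
        assert out.n_maps == 1
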