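import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmdpulse.errors import ExtractionError, LandmarkError
from hmdpulse.roi import (ExtractorConfig, LandmarkFrame, RoiTrack, compute_center,
                          center_distance, crop_roi, init_tracks, mouth_distortion,
                          process_video, update_center)
from hmdpulse.synth import SceneConfig, generate_clip, landmark_provider


class TestComputeCenter:
    def test_single_point(self):
        assert compute_center([(10.0, 20.0)]) == (10.0, 20.0)

    def test_symmetric_square(self):
        assert compute_center([(0, 0), (2, 0), (0, 2), (2, 2)]) == (1.0, 1.0)

    def test_matches_mean_oracle(self, rng):
        pts = [tuple(p) for p in rng.uniform(0, 100, size=(5, 2))]
        # oracle: explicit sum / N
        ox = sum(p[0] for p in pts) / 5.0
        oy = sum(p[1] for p in pts) / 5.0
        cx, cy = compute_center(pts)
        assert cx == pytest.approx(ox) and cy == pytest.approx(oy)

    def test_empty_raises(self):
        with pytest.raises(LandmarkError):
            compute_center([])


class TestCenterDistance:
    def test_zero(self):
        assert center_distance((100, 100), (100, 100)) == 0.0

    def test_3_4_5_triangle(self):
        assert center_distance((100, 100), (103, 104)) == pytest.approx(5.0)

    def test_unit_diagonal(self):
        assert center_distance((0, 0), (1, 1)) == pytest.approx(math.sqrt(2))

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
           st.floats(-1e3, 1e3), st.floats(-1e3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, x0, y0, x1, y1):
        assert center_distance((x0, y0), (x1, y1)) == pytest.approx(
            center_distance((x1, y1), (x0, y0)))


class TestUpdateCenter:
    def track(self, center=(100.0, 100.0), side=100.0):
        return RoiTrack(name="left_eye", center=center, side=side)

    def test_threshold_is_5_percent(self):
        assert self.track(side=100.0).threshold == pytest.approx(5.0)
        assert self.track(side=40.0).threshold == pytest.approx(2.0)

    def test_tie_at_threshold_keeps_center(self):
        # d == 5 == threshold exactly; strict "greater than" keeps old center
        out = update_center(self.track(), (103.0, 104.0), "replace")
        assert out.center == (100.0, 100.0)

    def test_replace_follows_motion(self):
        out = update_center(self.track(), (110.0, 110.0), "replace")
        assert out.center == (110.0, 110.0)

    def test_smooth_averages(self):
        out = update_center(self.track(), (110.0, 110.0), "smooth")
        assert out.center == (105.0, 105.0)

    def test_sub_threshold_ignored(self):
        out = update_center(self.track(), (101.0, 101.0), "replace")
        assert out.center == (100.0, 100.0)


class TestCropRoi:
    def test_eye_output_size(self, small_clip):
        tracks = init_tracks(small_clip.landmarks[0])
        crop = crop_roi(small_clip.frames[0], tracks["left_eye"], 100)
        assert crop.shape == (100, 100, 3)

    def test_lower_face_output_size(self, small_clip):
        tracks = init_tracks(small_clip.landmarks[0])
        crop = crop_roi(small_clip.frames[0], tracks["lower_face"], 400)
        assert crop.shape == (400, 400, 3)

    def test_uniform_frame_uniform_crop(self):
        frame = np.full((240, 320, 3), 77, dtype=np.uint8)
        track = RoiTrack(name="left_eye", center=(160.0, 120.0), side=48.0)
        crop = crop_roi(frame, track, 100)
        assert crop.shape == (100, 100, 3)
        assert np.all(crop == 77)

    def test_identity_crop_preserves_pixels(self, rng):
        frame = rng.integers(0, 256, (240, 320, 3), dtype=np.uint8)
        track = RoiTrack(name="left_eye", center=(160.0, 120.0), side=100.0)
        crop = crop_roi(frame, track, 100)
        np.testing.assert_array_equal(crop, frame[70:170, 110:210])

    def test_border_clamp_pads(self):
        frame = np.full((100, 100, 3), 9, dtype=np.uint8)
        track = RoiTrack(name="left_eye", center=(0.0, 0.0), side=60.0)
        crop = crop_roi(frame, track, 100)
        assert crop.shape == (100, 100, 3)
        assert np.all(crop == 9)

    def test_fully_outside_raises(self):
        frame = np.zeros((100, 100, 3), dtype=np.uint8)
        track = RoiTrack(name="left_eye", center=(500.0, 500.0), side=60.0)
        with pytest.raises(ExtractionError):
            crop_roi(frame, track, 100)


def brute_force_distortion(crop, center, radius, strength):
    """Per-pixel inverse-mapping oracle with manual bilinear sampling."""
    h, w = crop.shape[:2]
    cx, cy = center
    out = np.empty_like(crop, dtype=float)
    img = crop.astype(float)
    for y in range(h):
        for x in range(w):
            dx, dy = x - cx, y - cy
            r = math.hypot(dx, dy)
            scale = 1.0 if r >= radius else 1.0 - strength * (1.0 - r / radius)
            sx, sy = cx + dx * scale, cy + dy * scale
            sx = min(max(sx, 0.0), w - 1.0)
            sy = min(max(sy, 0.0), h - 1.0)
            x0, y0 = int(sx), int(sy)
            x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
            fx, fy = sx - x0, sy - y0
            for c in range(crop.shape[2]):
                top = img[y0, x0, c] * (1 - fx) + img[y0, x1, c] * fx
                bot = img[y1, x0, c] * (1 - fx) + img[y1, x1, c] * fx
                out[y, x, c] = top * (1 - fy) + bot * fy
    return out


class TestMouthDistortion:
    def test_strength_zero_identity(self, rng):
        crop = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        out = mouth_distortion(crop, (20.0, 20.0), 15.0, 0.0)
        np.testing.assert_array_equal(out, crop)

    def test_center_pixel_fixed(self, rng):
        crop = rng.integers(0, 256, (41, 41, 3), dtype=np.uint8)
        out = mouth_distortion(crop, (20.0, 20.0), 15.0, 0.3)
        np.testing.assert_array_equal(out[20, 20], crop[20, 20])

    def test_matches_brute_force_oracle(self, rng):
        crop = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        out = mouth_distortion(crop.astype(float), (16.0, 16.0), 12.0, 0.3)
        oracle = brute_force_distortion(crop, (16.0, 16.0), 12.0, 0.3)
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_checkerboard_magnifies_center(self):
        # single bright central square on black: its area must grow
        crop = np.zeros((33, 33, 3), dtype=np.uint8)
        crop[14:19, 14:19] = 255
        out = mouth_distortion(crop, (16.0, 16.0), 14.0, 0.3)
        assert (out[..., 0] > 127).sum() > (crop[..., 0] > 127).sum()


def _static_clip(**kwargs):
    defaults = dict(width=320, height=240, fps=30.0, duration=2.0,
                    heart_rate=72.0, pulse_amplitude=8.0, seed=5)
    defaults.update(kwargs)
    return generate_clip(SceneConfig(**defaults))


class TestProcessVideo:
    def test_static_face_constant_centers(self):
        clip = _static_clip()
        log = process_video(clip.frames, landmark_provider(clip))
        for roi_name in ("left_eye", "right_eye", "lower_face"):
            centers = {(row["cx"], row["cy"]) for row in log if row["roi"] == roi_name}
            assert len(centers) == 1

    def test_single_failure_reuses_previous(self):
        clip = _static_clip(duration=2.0)
        stream = landmark_provider(clip, fail_frames={30})
        log = process_video(clip.frames, stream)
        assert len(log) == len(clip.frames) * 3  # completed

    def test_consecutive_failures_abort(self):
        clip = _static_clip(duration=2.0)
        stream = landmark_provider(clip, fail_frames={30, 31})
        with pytest.raises(ExtractionError, match="frame 31"):
            process_video(clip.frames, stream,
                          ExtractorConfig(max_consecutive_failures=2))

    def test_output_layout_and_sizes(self, tmp_path):
        clip = _static_clip(duration=0.2)
        out = tmp_path / "rois"
        process_video(clip.frames, landmark_provider(clip), out_dir=str(out))
        eye_files = sorted((out / "left_eye").glob("left_eye_*.png"))
        assert len(eye_files) == len(clip.frames)
        assert eye_files[0].name == "left_eye_000000.png"
        from PIL import Image

        assert Image.open(eye_files[0]).size == (100, 100)
        lf = Image.open(out / "lower_face" / "lower_face_000000.png")
        assert lf.size == (400, 400)
        assert (out / "track_log.csv").exists()

    def test_grayscale_frames_saved_as_pgm(self, tmp_path):
        clip = _static_clip(duration=0.2)
        gray = clip.frames.mean(axis=-1).astype(np.uint8)
        out = tmp_path / "rois"
        process_video(gray, landmark_provider(clip), out_dir=str(out))
        assert len(list((out / "left_eye").glob("*.pgm"))) == len(gray)


class TestStabilizationProperties:
    def test_sub_threshold_noise_constant_centers(self):
        clip = _static_clip(duration=2.0)
        side = init_tracks(clip.landmarks[0])["left_eye"].side
        noise_sigma = 0.05 * side / 2.0 / 3.0  # 3-sigma stays under threshold/2
        stream = landmark_provider(clip, sigma=noise_sigma, seed=2)
        log = process_video(clip.frames, stream)
        for roi_name in ("left_eye", "right_eye", "lower_face"):
            rows = [row for row in log if row["roi"] == roi_name]
            first = (rows[0]["cx"], rows[0]["cy"])
            assert all((r["cx"], r["cy"]) == first for r in rows[1:])

    def test_step_translation_tracked_within_one_frame(self):
        clip = _static_clip(duration=1.0)
        tracks = init_tracks(clip.landmarks[0])
        step = 3.0 * tracks["left_eye"].threshold
        landmarks = list(landmark_provider(clip))
        shifted = [lm if i < 15 else lm.translated(step, 0.0)
                   for i, lm in enumerate(landmarks)]
        log = process_video(clip.frames, shifted,
                            ExtractorConfig(update_mode="replace"))
        rows = [r for r in log if r["roi"] == "left_eye"]
        assert rows[15]["cx"] == pytest.approx(rows[14]["cx"] + step)
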