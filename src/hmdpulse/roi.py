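"""Facial-ROI extraction with threshold stabilization.

Simulates head-mounted-display camera views from full-face video: per-frame
landmark groups give each ROI a center (the arithmetic mean of its points),
centers are stabilized against detection jitter by a movement threshold of
5% of the ROI side length, the two eye squares and the lower-face square
are cropped and resized to 100x100 and 400x400, and a radial magnification
("approximation") distortion is applied to the mouth region.

Coordinates are 0-based pixel indices, x right / y down; crops use
half-open ranges and are edge-padded where they touch frame borders.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, ExtractionError, LandmarkError

__all__ = [
    "LandmarkFrame", "RoiTrack", "ExtractorConfig",
    "compute_center", "center_distance", "update_center",
    "roi_side_lengths", "init_tracks", "crop_roi", "mouth_distortion",
    "process_video", "save_frame",
]

THRESHOLD_FRACTION = 0.05  # movement threshold as a fraction of ROI side
ROI_NAMES = ("left_eye", "right_eye", "lower_face")


@dataclass(frozen=True)
class LandmarkFrame:
    """Named facial point groups for one frame, in pixel coordinates."""

    left_eye: list[tuple[float, float]]
    right_eye: list[tuple[float, float]]
    mouth: list[tuple[float, float]]
    nose: list[tuple[float, float]]

    def group(self, name: str) -> list[tuple[float, float]]:
        return getattr(self, name)

    def validate(self):
        for name in ("left_eye", "right_eye", "mouth", "nose"):
            pts = self.group(name)
            if not len(pts):
                raise LandmarkError(f"empty landmark group {name!r}")
            if not np.all(np.isfinite(np.asarray(pts, dtype=float))):
                raise LandmarkError(f"non-finite coordinates in group {name!r}")

    def translated(self, dx: float, dy: float) -> "LandmarkFrame":
        move = lambda pts: [(x + dx, y + dy) for x, y in pts]
        return LandmarkFrame(move(self.left_eye), move(self.right_eye),
                             move(self.mouth), move(self.nose))


@dataclass(frozen=True)
class RoiTrack:
    """Stabilizer state for one ROI."""

    name: str
    center: tuple[float, float]
    side: float
    fail_count: int = 0

    def __post_init__(self):
        if self.side <= 0:
            raise ConfigurationError("ROI side must be positive")

    @property
    def threshold(self) -> float:
        return THRESHOLD_FRACTION * self.side


@dataclass(frozen=True)
class ExtractorConfig:
    update_mode: str = "replace"  # {"smooth", "replace"}
    eye_out: int = 100
    mouth_out: int = 400
    max_consecutive_failures: int = 2
    distortion_strength: float = 0.3
    apply_distortion: bool = True

    def __post_init__(self):
        if self.update_mode not in ("smooth", "replace"):
            raise ConfigurationError(f"unknown update_mode {self.update_mode!r}")
        if self.eye_out <= 0 or self.mouth_out <= 0:
            raise ConfigurationError("output sizes must be positive")
        if self.max_consecutive_failures < 1:
            raise ConfigurationError("max_consecutive_failures must be >= 1")
        if self.distortion_strength < 0:
            raise ConfigurationError("distortion strength must be >= 0")


def compute_center(points) -> tuple[float, float]:
    """Arithmetic-mean center of a point list."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise LandmarkError("cannot compute the center of an empty point list")
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def center_distance(prev: tuple[float, float], curr: tuple[float, float]) -> float:
    return math.hypot(curr[0] - prev[0], curr[1] - prev[1])


def update_center(track: RoiTrack, new_center: tuple[float, float],
                  mode: str = "replace") -> RoiTrack:
    """Apply the threshold rule: movement only when d exceeds the threshold.

    A distance exactly equal to the threshold keeps the previous center
    (strict "greater than").
    """
    d = center_distance(track.center, new_center)
    if d <= track.threshold:
        return track
    if mode == "smooth":
        cx = (track.center[0] + new_center[0]) / 2.0
        cy = (track.center[1] + new_center[1]) / 2.0
        return replace(track, center=(cx, cy))
    if mode == "replace":
        return replace(track, center=new_center)
    raise ConfigurationError(f"unknown update mode {mode!r}")


def roi_side_lengths(landmarks: LandmarkFrame) -> dict[str, float]:
    """Crop side lengths scaled to the face size.

    Eyes: 2.2x the landmark-group bounding-box diagonal.  Lower face: twice
    the vertical distance from the mouth center up to just below the eye
    line (a 5% margin below it), so the square's top edge sits under the
    eyes.
    """
    sides = {}
    for name in ("left_eye", "right_eye"):
        pts = np.asarray(landmarks.group(name), dtype=float)
        diag = math.hypot(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]))
        if diag <= 0:
            raise LandmarkError(f"degenerate {name} landmark group")
        sides[name] = 2.2 * diag
    eye_line_y = (compute_center(landmarks.left_eye)[1]
                  + compute_center(landmarks.right_eye)[1]) / 2.0
    mouth_cy = compute_center(landmarks.mouth)[1]
    drop = mouth_cy - eye_line_y
    if drop <= 0:
        raise LandmarkError("mouth center not below the eye line")
    sides["lower_face"] = 2.0 * 0.95 * drop
    return sides


def init_tracks(landmarks: LandmarkFrame) -> dict[str, RoiTrack]:
    landmarks.validate()
    sides = roi_side_lengths(landmarks)
    centers = {
        "left_eye": compute_center(landmarks.left_eye),
        "right_eye": compute_center(landmarks.right_eye),
        "lower_face": compute_center(landmarks.mouth),
    }
    return {name: RoiTrack(name=name, center=centers[name], side=sides[name])
            for name in ROI_NAMES}


def crop_roi(frame: np.ndarray, track: RoiTrack, out_size: int) -> np.ndarray:
    """Square crop of edge ``side`` around the track center, resized.

    Border-touching crops are clamped and edge-replicated to keep the
    output exactly ``out_size`` square.
    """
    h, w = frame.shape[:2]
    side = max(1, int(round(track.side)))
    x0 = int(round(track.center[0] - side / 2.0))
    y0 = int(round(track.center[1] - side / 2.0))
    x1, y1 = x0 + side, y0 + side
    if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
        raise ExtractionError(
            f"ROI {track.name!r} lies fully outside the {w}x{h} frame")
    pad_l, pad_t = max(0, -x0), max(0, -y0)
    pad_r, pad_b = max(0, x1 - w), max(0, y1 - h)
    crop = frame[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)]
    if pad_l or pad_t or pad_r or pad_b:
        pad_spec = [(pad_t, pad_b), (pad_l, pad_r)] + [(0, 0)] * (frame.ndim - 2)
        crop = np.pad(crop, pad_spec, mode="edge")
    if crop.shape[0] == out_size and crop.shape[1] == out_size:
        return crop.copy()
    out_shape = (out_size, out_size) + crop.shape[2:]
    resized = _sk_resize(crop.astype(float), out_shape, order=1,
                         preserve_range=True, anti_aliasing=False)
    if np.issubdtype(frame.dtype, np.integer):
        return np.clip(np.rint(resized), 0, 255).astype(frame.dtype)
    return resized.astype(frame.dtype)


def mouth_distortion(crop: np.ndarray, mouth_center: tuple[float, float],
                     radius: float, strength: float) -> np.ndarray:
    """Radial magnification inside ``radius`` around ``mouth_center``.

    Output pixels at distance r < radius sample the input at
    r' = r * (1 - strength * (1 - r/radius)) along the same ray (inverse
    mapping, bilinear); pixels at r >= radius are unchanged.  The effect
    makes the mouth look closer to the camera.
    """
    if radius <= 0:
        raise ConfigurationError("distortion radius must be positive")
    if strength < 0:
        raise ConfigurationError("distortion strength must be >= 0")
    if strength == 0:
        return crop.copy()
    h, w = crop.shape[:2]
    cx, cy = mouth_center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    scale = np.ones_like(r)
    inside = r < radius
    scale[inside] = 1.0 - strength * (1.0 - r[inside] / radius)
    src_x = cx + dx * scale
    src_y = cy + dy * scale
    coords = np.stack([src_y.ravel(), src_x.ravel()])

    def _remap(plane: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(plane.astype(float), coords, order=1,
                                       mode="nearest").reshape(h, w)

    if crop.ndim == 2:
        out = _remap(crop)
    else:
        out = np.stack([_remap(crop[..., c]) for c in range(crop.shape[-1])], axis=-1)
    if np.issubdtype(crop.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(crop.dtype)
    return out.astype(crop.dtype)


def save_frame(path: str, image: np.ndarray):
    """Write RGB frames as PNG, single-channel frames as PGM."""
    from PIL import Image

    arr = image
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        Image.fromarray(arr, mode="L").save(path)
    else:
        Image.fromarray(arr, mode="RGB").save(path)


def _frame_ext(frame: np.ndarray) -> str:
    return "pgm" if frame.ndim == 2 else "png"


def process_video(frames, landmark_stream, config: ExtractorConfig | None = None,
                  out_dir: str | None = None, on_crop=None,
                  mouth_nose_radius: float | None = None):
    """Stream frames through the stabilized ROI extractor.

    Parameters
    ----------
    frames : iterable of H x W x 3 (or H x W) arrays
        Consumed lazily; only the current frame is held.
    landmark_stream : iterable of LandmarkFrame or None
        ``None`` marks a detection failure for that frame: the last
        detected coordinates are reused, except when failures occur
        ``max_consecutive_failures`` times in a row, which aborts.
    out_dir : str, optional
        If given, per-ROI subdirectories are created and every crop is
        written as ``<roi>/<roi>_<frame:06d>.png`` (``.pgm`` for
        single-channel frames); a ``track_log.csv`` is written alongside.
    on_crop : callable, optional
        ``on_crop(frame_idx, roi_name, crop)`` for in-memory consumers.

    Returns
    -------
    list of dict
        Track log rows: frame, roi, cx, cy, d, moved.
    """
    config = config or ExtractorConfig()
    tracks: dict[str, RoiTrack] | None = None
    last_landmarks: LandmarkFrame | None = None
    fail_count = 0
    log: list[dict] = []
    writer = None
    csv_file = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name in ROI_NAMES:
            os.makedirs(os.path.join(out_dir, name), exist_ok=True)
        csv_file = open(os.path.join(out_dir, "track_log.csv"), "w", newline="")
        writer = csv.DictWriter(csv_file, fieldnames=["frame", "roi", "cx", "cy", "d", "moved"])
        writer.writeheader()

    try:
        for idx, (frame, lm) in enumerate(zip(frames, landmark_stream)):
            if lm is None:
                fail_count += 1
                if fail_count >= config.max_consecutive_failures:
                    raise ExtractionError(
                        f"landmark detection failed {fail_count} consecutive times, "
                        f"last at frame {idx}; aborting")
                if last_landmarks is None:
                    raise ExtractionError(f"no landmarks available at frame {idx}")
                lm = last_landmarks
            else:
                fail_count = 0
                lm.validate()
                last_landmarks = lm

            if tracks is None:
                tracks = init_tracks(lm)
                new_centers = {name: tracks[name].center for name in ROI_NAMES}
                dists = {name: 0.0 for name in ROI_NAMES}
                moved = {name: True for name in ROI_NAMES}
            else:
                new_centers = {
                    "left_eye": compute_center(lm.left_eye),
                    "right_eye": compute_center(lm.right_eye),
                    "lower_face": compute_center(lm.mouth),
                }
                dists, moved = {}, {}
                for name in ROI_NAMES:
                    d = center_distance(tracks[name].center, new_centers[name])
                    updated = update_center(tracks[name], new_centers[name],
                                            config.update_mode)
                    dists[name] = d
                    moved[name] = updated.center != tracks[name].center
                    tracks[name] = updated

            for name in ROI_NAMES:
                out_size = config.mouth_out if name == "lower_face" else config.eye_out
                crop = crop_roi(frame, tracks[name], out_size)
                if name == "lower_face" and config.apply_distortion \
                        and config.distortion_strength > 0:
                    track = tracks[name]
                    if mouth_nose_radius is not None:
                        radius_src = mouth_nose_radius
                    else:
                        radius_src = center_distance(compute_center(lm.mouth),
                                                     compute_center(lm.nose))
                    scale = out_size / max(1.0, track.side)
                    crop = mouth_distortion(crop, (out_size / 2.0, out_size / 2.0),
                                            max(1.0, radius_src * scale),
                                            config.distortion_strength)
                row = {"frame": idx, "roi": name,
                       "cx": tracks[name].center[0], "cy": tracks[name].center[1],
                       "d": dists[name], "moved": moved[name]}
                log.append(row)
                if writer is not None:
                    writer.writerow(row)
                if out_dir is not None:
                    fname = f"{name}_{idx:06d}.{_frame_ext(frame)}"
                    save_frame(os.path.join(out_dir, name, fname), crop)
                if on_crop is not None:
                    on_crop(idx, name, crop)
    finally:
        if csv_file is not None:
            csv_file.close()
    return log
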