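"""Synthetic pulse-bearing face videos with ground-truth landmarks and PPG.

Stands in for real face-video datasets in every test: an ellipsoidal skin
region whose mean color is modulated by a pulse waveform at a known heart
rate, landmark groups (two eyes, mouth outline, nose tip) riding rigidly on
a seeded random-walk head translation, plus optional per-pixel noise.

The pulse waveform is ``w(theta) = sin(theta) + 0.3*sin(2*theta)`` — the
second harmonic makes individual beats asymmetric and peak-detectable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .hr_signal import PpgTrace
from .roi import LandmarkFrame

__all__ = ["SceneConfig", "SyntheticClip", "pulse_waveform", "generate_clip",
           "landmark_provider", "write_clip"]

SKIN_COLOR = np.array([198.0, 144.0, 122.0])  # base RGB of the face ellipse
BACKGROUND = np.array([40.0, 40.0, 44.0])


@dataclass(frozen=True)
class SceneConfig:
    width: int = 640
    height: int = 480
    fps: float = 30.0
    duration: float = 4.0
    heart_rate: float = 72.0
    pulse_amplitude: float = 8.0
    noise_sigma: float = 0.0
    jitter_step: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("frame dimensions must be positive")
        if self.fps <= 0:
            raise ConfigurationError("fps must be positive")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if not 45.0 <= self.heart_rate <= 240.0:
            raise ConfigurationError("heart_rate must lie in [45, 240] BPM")
        if self.pulse_amplitude < 0 or self.noise_sigma < 0 or self.jitter_step < 0:
            raise ConfigurationError("amplitudes must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


@dataclass
class SyntheticClip:
    frames: np.ndarray  # (T, H, W, 3) uint8
    landmarks: list[LandmarkFrame]
    ppg: PpgTrace
    heart_rate: float
    config: SceneConfig = None

    def __post_init__(self):
        if not (len(self.frames) == len(self.landmarks) == self.ppg.samples.size):
            raise ValueError("frame, landmark and PPG counts must agree")


def pulse_waveform(theta: np.ndarray) -> np.ndarray:
    """Asymmetric pulse shape: fundamental plus a 0.3-weight second harmonic."""
    return np.sin(theta) + 0.3 * np.sin(2.0 * theta)


def _face_geometry(config: SceneConfig):
    a = 0.22 * config.width   # ellipse semi-axes
    b = 0.35 * config.height
    return a, b


def _landmarks_at(center: tuple[float, float], a: float, b: float) -> LandmarkFrame:
    cx, cy = center
    eye_dx, eye_dy = 0.40 * a, -0.36 * b
    box = 0.09 * a

    def eye(cx_eye):
        return [(cx_eye - box, cy + eye_dy - box), (cx_eye + box, cy + eye_dy - box),
                (cx_eye - box, cy + eye_dy + box), (cx_eye + box, cy + eye_dy + box)]

    mouth_cy = cy + 0.50 * b
    mw, mh = 0.36 * a, 0.10 * b
    angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    mouth = [(cx + mw * np.cos(t), mouth_cy + mh * np.sin(t)) for t in angles]
    nose = [(cx, cy + 0.18 * b)]
    # viewer's perspective: subject's left eye appears on the image right
    return LandmarkFrame(left_eye=eye(cx + eye_dx), right_eye=eye(cx - eye_dx),
                         mouth=mouth, nose=nose)


def generate_clip(config: SceneConfig) -> SyntheticClip:
    """Render the clip; identical configs (and seeds) give identical bits."""
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    a, b = _face_geometry(config)
    base_center = np.array([config.width / 2.0, config.height / 2.0])

    steps = rng.normal(0.0, config.jitter_step, size=(n, 2)) if config.jitter_step > 0 \
        else np.zeros((n, 2))
    steps[0] = 0.0
    positions = base_center + np.cumsum(steps, axis=0)

    t = np.arange(n) / config.fps
    theta = 2.0 * np.pi * (config.heart_rate / 60.0) * t
    # the returned PPG is the noise-free modulation actually added to the skin
    ppg_samples = config.pulse_amplitude * pulse_waveform(theta)

    yy, xx = np.mgrid[0 : config.height, 0 : config.width].astype(float)
    frames = np.empty((n, config.height, config.width, 3), dtype=np.uint8)
    landmarks: list[LandmarkFrame] = []
    for i in range(n):
        cx, cy = positions[i]
        mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        frame = np.empty((config.height, config.width, 3))
        frame[:] = BACKGROUND
        skin = SKIN_COLOR + ppg_samples[i]
        frame[mask] = skin
        if config.noise_sigma > 0:
            frame += rng.normal(0.0, config.noise_sigma, size=frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        landmarks.append(_landmarks_at((cx, cy), a, b))

    ppg = PpgTrace(samples=ppg_samples, fs=config.fps)
    return SyntheticClip(frames=frames, landmarks=landmarks, ppg=ppg,
                         heart_rate=config.heart_rate, config=config)


def landmark_provider(clip: SyntheticClip, sigma: float = 0.0, seed: int = 0,
                      fail_frames: set[int] | None = None):
    """Yield per-frame landmarks, optionally noise-perturbed.

    ``fail_frames`` marks frames as detection failures (yields ``None``)
    to exercise the extractor's failure policy.
    """
    rng = np.random.default_rng(seed)
    fail_frames = fail_frames or set()
    for i, lm in enumerate(clip.landmarks):
        if i in fail_frames:
            yield None
            continue
        if sigma <= 0:
            yield lm
            continue
        perturb = lambda pts: [
            (x + rng.normal(0, sigma), y + rng.normal(0, sigma)) for x, y in pts
        ]
        yield LandmarkFrame(perturb(lm.left_eye), perturb(lm.right_eye),
                            perturb(lm.mouth), perturb(lm.nose))


def write_clip(clip: SyntheticClip, out_dir: str):
    """Write numbered PNG frames, a UBFC-style ground-truth text file and
    the ground-truth landmark stream (landmarks.json, consumed by the
    ``extract`` CLI's synthetic landmark source)."""
    import json

    from .io import write_frames_dir, write_ubfc_trace

    os.makedirs(out_dir, exist_ok=True)
    write_frames_dir(clip.frames, out_dir)
    fps = clip.ppg.fs
    times = np.arange(clip.ppg.samples.size) / fps
    bpm = np.full(clip.ppg.samples.size, clip.heart_rate)
    write_ubfc_trace(os.path.join(out_dir, "ground_truth.txt"),
                     clip.ppg.samples, bpm, times)
    records = [
        {name: [list(map(float, p)) for p in lm.group(name)]
         for name in ("left_eye", "right_eye", "mouth", "nose")}
        for lm in clip.landmarks
    ]
    with open(os.path.join(out_dir, "landmarks.json"), "w") as fh:
        json.dump(records, fh)
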