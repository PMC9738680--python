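"""PPG trace handling: frame-rate rescaling, filtering, peak-based BPM.

The BPM conversion contract is deterministic and fully specified here:
per window the trace is band-pass filtered to the plausible pulse band
(0.75-4 Hz), peaks are local maxima above an adaptive rolling threshold
with a refractory distance of 60/240 s, and the window BPM is
60 / median inter-beat interval.  Windows with fewer than three peaks, or
a BPM outside [30, 250], are marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import WindowingError

__all__ = ["PpgTrace", "BpmSeries", "resample_fps", "resample_indices", "ppg_to_bpm",
           "bandpass_filter", "detect_peaks"]

PULSE_BAND = (0.75, 4.0)  # Hz
MIN_PEAK_DISTANCE_S = 60.0 / 240.0  # refractory period at the 240 BPM ceiling
BPM_VALID_RANGE = (30.0, 250.0)


@dataclass
class PpgTrace:
    """Uniformly sampled PPG waveform."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 2:
            raise ValueError("a trace needs at least two samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class BpmSeries:
    """Windowed BPM estimates with validity flags."""

    times: np.ndarray
    bpm: np.ndarray
    valid: np.ndarray = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.bpm)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def valid_bpm(self) -> np.ndarray:
        return self.bpm[self.valid]

    def mean_bpm(self) -> float:
        vals = self.valid_bpm
        return float(vals.mean()) if vals.size else float("nan")


def resample_indices(n_frames: int, src_fps: float, dst_fps: float = 30.0) -> np.ndarray:
    """Nearest-source-frame index map for frame-rate rescaling."""
    if src_fps <= 0 or dst_fps <= 0:
        raise ValueError("frame rates must be positive")
    n_out = int(round(n_frames * dst_fps / src_fps))
    idx = np.floor(np.arange(n_out) * src_fps / dst_fps + 0.5).astype(int)
    return np.clip(idx, 0, n_frames - 1)


def resample_fps(frames, src_fps: float, dst_fps: float = 30.0):
    """Rescale a frame sequence to ``dst_fps`` by nearest-frame selection."""
    frames = list(frames) if not isinstance(frames, np.ndarray) else frames
    idx = resample_indices(len(frames), src_fps, dst_fps)
    if isinstance(frames, np.ndarray):
        return frames[idx]
    return [frames[i] for i in idx]


def bandpass_filter(samples: np.ndarray, fs: float,
                    band: tuple[float, float] = PULSE_BAND) -> np.ndarray:
    """Zero-phase Butterworth band-pass restricted to the pulse band."""
    samples = np.asarray(samples, dtype=float)
    nyq = fs / 2.0
    lo, hi = band
    hi = min(hi, 0.99 * nyq)
    if lo >= hi:
        # band collapses at very low sampling rates; fall back to detrending
        return samples - samples.mean()
    sos = sps.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    padlen = min(samples.size - 1, 3 * 10)
    return sps.sosfiltfilt(sos, samples, padlen=padlen)


def _rolling(values: np.ndarray, win: int, fn) -> np.ndarray:
    win = max(1, win)
    pad = win // 2
    padded = np.pad(values, (pad, win - 1 - pad), mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, win)
    return fn(view, axis=-1)


def detect_peaks(filtered: np.ndarray, fs: float) -> np.ndarray:
    """Local maxima above a rolling mean + 0.5*SD threshold (2 s window)."""
    win = int(round(2.0 * fs))
    threshold = _rolling(filtered, win, np.mean) + 0.5 * _rolling(filtered, win, np.std)
    distance = max(1, int(round(MIN_PEAK_DISTANCE_S * fs)))
    peaks, _ = sps.find_peaks(filtered, height=threshold, distance=distance)
    return peaks


def ppg_to_bpm(trace: PpgTrace, window_s: float = 10.0, stride_s: float | None = None) -> BpmSeries:
    """Convert a PPG trace to a windowed BPM series.

    Raises
    ------
    WindowingError
        If the trace is shorter than one window.
    """
    if stride_s is None:
        stride_s = window_s
    win = int(round(window_s * trace.fs))
    stride = max(1, int(round(stride_s * trace.fs)))
    if trace.samples.size < win:
        raise WindowingError(
            f"trace of {trace.duration:.2f}s shorter than window {window_s:.2f}s")

    times, bpms, valid = [], [], []
    for start in range(0, trace.samples.size - win + 1, stride):
        chunk = trace.samples[start : start + win]
        center_t = (start + win / 2.0) / trace.fs
        filtered = bandpass_filter(chunk, trace.fs)
        if np.ptp(filtered) <= 1e-12:
            times.append(center_t); bpms.append(np.nan); valid.append(False)
            continue
        peaks = detect_peaks(filtered, trace.fs)
        if peaks.size < 3:
            times.append(center_t); bpms.append(np.nan); valid.append(False)
            continue
        ibi = np.diff(peaks) / trace.fs
        bpm = 60.0 / float(np.median(ibi))
        ok = BPM_VALID_RANGE[0] <= bpm <= BPM_VALID_RANGE[1]
        times.append(center_t)
        bpms.append(bpm if ok else np.nan)
        valid.append(ok)
    return BpmSeries(np.array(times), np.array(bpms), np.array(valid))
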