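"""Causal Eulerian motion magnification.

Each frame is spatially decomposed (Gaussian pyramid, keeping the deepest —
edge-free — level), temporally filtered by a causal band-pass built from
two first-order IIR lowpass filters differenced (no future samples), and
``alpha`` times the band-passed component is added back at full resolution.
Chrominance/color amplification is not used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import pyramid_reduce, resize as _sk_resize

from .errors import ConfigurationError

__all__ = ["MagnifyConfig", "CausalMagnifier", "magnify_stream", "iir_bandpass_coeff"]


@dataclass(frozen=True)
class MagnifyConfig:
    amplification: float = 10.0
    band: tuple[float, float] = (0.5, 4.0)
    levels: int = 4

    def __post_init__(self):
        if self.amplification < 0:
            raise ConfigurationError("amplification must be >= 0")
        if self.levels < 1:
            raise ConfigurationError("levels must be >= 1")
        lo, hi = self.band
        if not 0 <= lo < hi:
            raise ConfigurationError("band must satisfy 0 <= f_lo < f_hi")

    def validate_against(self, fps: float):
        if self.band[1] > fps / 2.0:
            raise ConfigurationError(
                f"band upper edge {self.band[1]} Hz exceeds Nyquist {fps / 2.0} Hz")


def iir_bandpass_coeff(freq: float, fps: float) -> float:
    """One-pole lowpass smoothing coefficient for a given cutoff."""
    return 1.0 - np.exp(-2.0 * np.pi * freq / fps)


class CausalMagnifier:
    """Streaming magnifier: ``push`` consumes one frame, returns one frame."""

    def __init__(self, fps: float, config: MagnifyConfig | None = None):
        config = config or MagnifyConfig()
        config.validate_against(fps)
        self.config = config
        self.a_lo = iir_bandpass_coeff(config.band[0], fps)
        self.a_hi = iir_bandpass_coeff(config.band[1], fps)
        self._state_lo: np.ndarray | None = None
        self._state_hi: np.ndarray | None = None

    def _decompose(self, frame: np.ndarray) -> np.ndarray:
        low = frame
        for _ in range(self.config.levels - 1):
            low = pyramid_reduce(low, downscale=2,
                                 channel_axis=-1 if low.ndim == 3 else None)
        return low

    def push(self, frame: np.ndarray) -> np.ndarray:
        if self.config.amplification == 0:
            return frame.copy()
        dtype = frame.dtype
        as_float = frame.astype(float)
        low = self._decompose(as_float)
        if self._state_lo is None:
            self._state_lo = low.copy()
            self._state_hi = low.copy()
        self._state_lo += self.a_lo * (low - self._state_lo)
        self._state_hi += self.a_hi * (low - self._state_hi)
        band = self._state_hi - self._state_lo
        if band.shape != as_float.shape:
            band = _sk_resize(band, as_float.shape, order=1, preserve_range=True,
                              anti_aliasing=False)
        out = as_float + self.config.amplification * band
        if np.issubdtype(dtype, np.integer):
            return np.clip(np.rint(out), 0, 255).astype(dtype)
        return out.astype(dtype)


def magnify_stream(frames, fps: float, config: MagnifyConfig | None = None):
    """Magnify a frame sequence; output length equals input length."""
    magnifier = CausalMagnifier(fps, config)
    return [magnifier.push(np.asarray(f)) for f in frames]
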