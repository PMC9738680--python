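"""Feature-image construction and the depthwise-separable regression CNN.

A feature image packs one second of an ROI stream into a 25x25x3 tensor:
each frame's lowest Gaussian-pyramid band (5x5 per channel) is flattened
row-major into a 25-vector column, the columns are linearly resampled to 25
along time, and every pixel row is band-pass filtered in the frequency
domain (rFFT mask, 0.75-4 Hz inclusive of edge bins).

The regression network is a depthwise-separable stack: a full 5x5
convolution to 96 channels, alternating
depthwise 3x3 / pointwise 1x1 convolutions (96-96-96-128-128) with batch
normalization and ReLU, a 2x2 average pool to resolution one, FC 128x192,
dropout 0.6, FC 192x1 and a Euclidean-distance loss.  Training labels are
BPM values affinely normalized so 45 BPM maps to 0 and 240 BPM to 1; the
PPG-target variant widens the head to 25 outputs (one per time column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import pyramid_reduce, resize as _sk_resize

from . import nn
from .errors import ConfigurationError, WindowingError
from .hr_signal import PpgTrace

__all__ = [
    "BPM_RANGE", "FEATURE_BAND", "FeatureImage", "EvmModelConfig",
    "normalize_bpm", "denormalize_bpm", "spatial_lowest_band",
    "bandpass_rows", "build_feature_image", "sliding_windows",
    "EvmNet", "build_evm_network", "train_evm", "predict_evm",
]

BPM_RANGE = (45.0, 240.0)
FEATURE_BAND = (0.75, 4.0)  # Hz
FEATURE_SIZE = 25           # pixels axis and time axis
BAND_SIDE = 5               # lowest-band spatial side (5*5 == 25 pixel rows)


def normalize_bpm(bpm) -> np.ndarray | float:
    """Affine map of [45, 240] BPM onto [0, 1]; out-of-range values clamp."""
    arr = np.asarray(bpm, dtype=float)
    lo, hi = BPM_RANGE
    if np.any(arr < lo) or np.any(arr > hi):
        warnings.warn(f"BPM outside [{lo}, {hi}] clamped before normalization",
                      stacklevel=2)
        arr = np.clip(arr, lo, hi)
    out = (arr - lo) / (hi - lo)
    return float(out) if np.isscalar(bpm) else out


def denormalize_bpm(value) -> np.ndarray | float:
    arr = np.asarray(value, dtype=float)
    lo, hi = BPM_RANGE
    out = lo + arr * (hi - lo)
    return float(out) if np.isscalar(value) else out


def spatial_lowest_band(roi_frame: np.ndarray) -> np.ndarray:
    """Lowest Gaussian-pyramid band of a (square) ROI frame, as 5x5xC.

    Blur-and-halve until the smaller spatial dimension is <= 8, then resize
    to exactly 5x5 per channel.
    """
    band = np.asarray(roi_frame, dtype=float)
    channel_axis = -1 if band.ndim == 3 else None
    while min(band.shape[:2]) > 8:
        band = pyramid_reduce(band, downscale=2, channel_axis=channel_axis,
                              preserve_range=True)
    target = (BAND_SIDE, BAND_SIDE) + band.shape[2:]
    if band.shape[:2] != (BAND_SIDE, BAND_SIDE):
        band = _sk_resize(band, target, order=1, preserve_range=True,
                          anti_aliasing=False)
    return band


def bandpass_rows(rows: np.ndarray, fs: float,
                  band: tuple[float, float] = FEATURE_BAND) -> np.ndarray:
    """Zero out rFFT bins outside ``band`` (edge bins inclusive), per row."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spectrum = np.fft.rfft(rows, axis=-1)
    spectrum *= mask
    return np.fft.irfft(spectrum, n=n, axis=-1)


@dataclass(frozen=True)
class FeatureImage:
    """25 (pixels) x 25 (time) x 3 (channels) band-passed color variations."""

    data: np.ndarray
    start_frame: int = 0
    fps: float = 30.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape != (FEATURE_SIZE, FEATURE_SIZE, 3):
            raise ValueError(f"feature image must be 25x25x3, got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("feature image contains non-finite values")
        object.__setattr__(self, "data", data)

    def to_uint8(self) -> np.ndarray:
        """Rescaled copy for PNG inspection."""
        data = self.data
        span = np.ptp(data)
        if span == 0:
            return np.zeros(data.shape, dtype=np.uint8)
        return np.clip(np.rint(255 * (data - data.min()) / span), 0, 255).astype(np.uint8)


def build_feature_image(roi_frames, fps: float, start_frame: int = 0) -> FeatureImage:
    """Build one feature image from one second of ROI frames."""
    frames = [np.asarray(f, dtype=float) for f in roi_frames]
    if len(frames) < max(2, int(round(fps))):
        raise WindowingError(
            f"need one second of frames ({int(round(fps))} at {fps} FPS), "
            f"got {len(frames)}")
    columns = np.stack(
        [spatial_lowest_band(f).reshape(FEATURE_SIZE, -1, order="C") for f in frames],
        axis=1,
    )  # (25 pixels, T frames, C channels)
    if columns.ndim == 2:
        columns = columns[:, :, None].repeat(3, axis=2)
    t_src = columns.shape[1]
    resample = nn.time_resize_matrix(t_src, FEATURE_SIZE)  # (25, T)
    resampled = np.einsum("ptc,st->psc", columns, resample)
    # rows now span exactly one second -> effective sampling rate is 25 Hz
    filtered = bandpass_rows(resampled.transpose(0, 2, 1), fs=float(FEATURE_SIZE))
    return FeatureImage(data=filtered.transpose(0, 2, 1), start_frame=start_frame,
                        fps=fps)


def sliding_windows(n_frames: int, fps: float, stride_s: float = 1.0):
    """Yield (start, stop) index pairs for one-second windows."""
    win = int(round(fps))
    stride = max(1, int(round(stride_s * fps)))
    if n_frames < win:
        raise WindowingError(f"stream of {n_frames} frames shorter than one window")
    for start in range(0, n_frames - win + 1, stride):
        yield start, start + win


@dataclass(frozen=True)
class EvmModelConfig:
    target: str = "bpm"  # {"bpm", "ppg"}
    dropout: float = 0.6
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    stride_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.target not in ("bpm", "ppg"):
            raise ConfigurationError(f"unknown target {self.target!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")

    @property
    def out_dim(self) -> int:
        return FEATURE_SIZE if self.target == "ppg" else 1


class EvmNet(nn.Module):
    """The depthwise-separable regression CNN (input 3x25x25)."""

    def __init__(self, config: EvmModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)

        def block(layer, channels):
            return [layer, nn.BatchNorm(channels)]

        # (kind, in, out, stride, pad) chosen to realize the size trace:
        # 25 -conv5/p1-> 23 -dw3/p0-> 21 -pw-> 21 -dw3/s2p1-> 11 -pw-> 11
        # -dw3/s2p1-> 6 -pw-> 6 -dw3/s2p1-> 3 -pw-> 3 -dw3/s2p1-> 2 -pw-> 2
        layers: list[nn.Module] = []
        layers += block(nn.Conv2d(3, 96, 5, rng, stride=1, pad=1), 96)
        layers += block(nn.DepthwiseConv2d(96, 3, rng, stride=1, pad=0), 96)
        layers += block(nn.Conv2d(96, 96, 1, rng), 96)
        layers += block(nn.DepthwiseConv2d(96, 3, rng, stride=2, pad=1), 96)
        layers += block(nn.Conv2d(96, 96, 1, rng), 96)
        layers += block(nn.DepthwiseConv2d(96, 3, rng, stride=2, pad=1), 96)
        layers += block(nn.Conv2d(96, 128, 1, rng), 128)
        layers += block(nn.DepthwiseConv2d(128, 3, rng, stride=2, pad=1), 128)
        layers += block(nn.Conv2d(128, 128, 1, rng), 128)
        layers += block(nn.DepthwiseConv2d(128, 3, rng, stride=2, pad=1), 128)
        layers += block(nn.Conv2d(128, 128, 1, rng), 128)
        self.conv_layers = layers
        self.pool = nn.AvgPool2d(2)
        self.fc1 = nn.Linear(128, 192, rng)
        self.dropout = nn.Dropout(config.dropout, np.random.default_rng(config.seed + 1))
        self.fc2 = nn.Linear(192, config.out_dim, rng)

    def features(self, x: nn.Tensor, probe: list | None = None) -> nn.Tensor:
        for i in range(0, len(self.conv_layers), 2):
            conv, bn = self.conv_layers[i], self.conv_layers[i + 1]
            x = bn(conv(x)).relu()
            if probe is not None:
                probe.append(x.shape)
        x = self.pool(x)
        if probe is not None:
            probe.append(x.shape)
        return x.reshape(x.shape[0], -1)

    def forward(self, x: nn.Tensor, probe: list | None = None) -> nn.Tensor:
        x = self.features(x, probe)
        x = self.fc1(x)
        if probe is not None:
            probe.append(x.shape)
        x = self.dropout(x)
        out = self.fc2(x)
        if probe is not None:
            probe.append(out.shape)
        return out

    def shape_probe(self) -> list[tuple[int, ...]]:
        """Intermediate output shapes for a single 25x25x3 input."""
        probe: list[tuple[int, ...]] = []
        mode = self.training
        self.eval()
        self.forward(nn.Tensor(np.zeros((1, 3, FEATURE_SIZE, FEATURE_SIZE))), probe)
        self.train(mode)
        return probe


def build_evm_network(config: EvmModelConfig | None = None) -> EvmNet:
    return EvmNet(config or EvmModelConfig())


def _as_input_batch(features) -> np.ndarray:
    arrs = []
    for f in features:
        data = f.data if isinstance(f, FeatureImage) else np.asarray(f, dtype=float)
        arrs.append(data.transpose(2, 0, 1))  # channels first
    return np.stack(arrs)


def train_evm(dataset, config: EvmModelConfig | None = None,
              model: EvmNet | None = None) -> tuple[EvmNet, list[float]]:
    """Train the regression network; returns (model, per-epoch loss history).

    ``dataset`` is a sequence of (feature_image, label) pairs where labels
    are normalized BPM scalars (bpm target) or 25-sample PPG vectors (ppg
    target).
    """
    config = config or EvmModelConfig()
    if len(dataset) == 0:
        raise ConfigurationError("empty training dataset")
    model = model or build_evm_network(config)
    inputs = _as_input_batch([f for f, _ in dataset])
    labels = np.stack([np.atleast_1d(np.asarray(l, dtype=float)) for _, l in dataset])
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    model.train()
    for _ in range(config.epochs):
        order = rng.permutation(len(dataset))
        epoch_losses = []
        for start in range(0, len(dataset), config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = model(nn.Tensor(inputs[idx]))
            loss = nn.euclidean_loss(pred, labels[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    model.eval()
    return model, history


def predict_evm(model: EvmNet, roi_frames, fps: float,
                stride_s: float | None = None):
    """Slide one-second windows over an ROI stream and predict per window.

    Returns (times, bpm_series) for the bpm target, or a
    :class:`~hmdpulse.hr_signal.PpgTrace` for the ppg target.
    """
    config = model.config
    stride_s = config.stride_s if stride_s is None else stride_s
    frames = list(roi_frames)
    model.eval()
    windows, times = [], []
    for start, stop in sliding_windows(len(frames), fps, stride_s):
        fi = build_feature_image(frames[start:stop], fps, start_frame=start)
        windows.append(fi)
        times.append((start + stop) / 2.0 / fps)
    preds = model(nn.Tensor(_as_input_batch(windows))).data
    if config.target == "bpm":
        return np.array(times), denormalize_bpm(preds[:, 0])
    samples = preds.reshape(-1)
    return PpgTrace(samples=samples, fs=FEATURE_SIZE / max(stride_s, 1e-9))
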