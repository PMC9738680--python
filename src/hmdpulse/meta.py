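"""Encoder/LSTM heart-rate estimator with transductive adaptation.

Three ROI crops are composed into one 64x64 face-like frame (eyes
side-by-side above the lower face).  Sixty-frame sequences feed a five-block
convolutional encoder (widths 32-48-64-80-120, each block Conv2D +
BatchNorm + AvgPool + ReLU with 1x1-projected shortcut connections), a
bidirectional LSTM estimator with an ordinal 40-threshold output, and a
four-block Conv1D synthetic-gradient generator (temporal encoder-decoder
60-40-20-40-60 over 120 channels) that learns to mimic the true encoder
gradients so the encoder can adapt on unlabeled sequences at test time.

Dataset routing follows an 88/12 train/test split, with 22% of the
training partition forwarded to pre-training, itself divided 55/45 into
query and support sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .errors import ConfigurationError
from .hr_signal import PpgTrace, ppg_to_bpm

__all__ = [
    "SEQUENCE_LENGTH", "COMPOSED_SIZE", "ORDINAL_LEVELS",
    "SequenceSample", "SplitPlan", "MetaModelConfig",
    "compose_frame", "build_sequences", "split_dataset",
    "ordinal_encode", "ordinal_decode", "normalize_ppg_sequence",
    "MetaNet", "build_meta_network", "train_meta", "adapt_and_predict",
]

SEQUENCE_LENGTH = 60
COMPOSED_SIZE = 64
ORDINAL_LEVELS = 40
ENCODER_WIDTHS = (32, 48, 64, 80, 120)
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


def compose_frame(left_eye: np.ndarray, right_eye: np.ndarray,
                  lower_face: np.ndarray, grayscale: bool = False) -> np.ndarray:
    """Assemble the three ROI crops into one 64x64 face-like frame.

    The right eye sits on the image-left (mirroring a viewed face), the
    lower face is resized to the eye band's width and stacked below, and
    the composite is resized to 64x64.
    """
    le, re, lf = (np.asarray(a, dtype=float) for a in (left_eye, right_eye, lower_face))
    if le.shape != re.shape:
        raise ConfigurationError(f"eye crop shapes differ: {le.shape} vs {re.shape}")
    if le.ndim != lf.ndim:
        raise ConfigurationError("eye and lower-face crops must share channel layout")
    band = np.concatenate([re, le], axis=1)  # (eye_h, 2*eye_w, C)
    width = band.shape[1]
    lf_resized = _sk_resize(lf, (width // 2, width) + lf.shape[2:], order=1,
                            preserve_range=True, anti_aliasing=False)
    composite = np.concatenate([band, lf_resized], axis=0)
    out = _sk_resize(composite, (COMPOSED_SIZE, COMPOSED_SIZE) + composite.shape[2:],
                     order=1, preserve_range=True, anti_aliasing=False)
    if grayscale and out.ndim == 3:
        out = out @ GRAY_WEIGHTS
    if out.ndim == 2:
        out = out[..., None]
    return out


@dataclass
class SequenceSample:
    """Sixty composed frames with (for training) their ground-truth PPG."""

    frames: np.ndarray  # (60, 64, 64, C)
    ppg: np.ndarray | None = None
    heart_rate: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.shape[0] != SEQUENCE_LENGTH:
            raise ValueError(f"sequence length must be {SEQUENCE_LENGTH}")
        if self.frames.shape[1:3] != (COMPOSED_SIZE, COMPOSED_SIZE):
            raise ValueError(f"frames must be {COMPOSED_SIZE}x{COMPOSED_SIZE}")
        if self.ppg is not None:
            self.ppg = np.asarray(self.ppg, dtype=float).ravel()
            if self.ppg.size != SEQUENCE_LENGTH:
                raise ValueError("ppg must have one sample per frame")

    @property
    def channels(self) -> int:
        return self.frames.shape[-1]


def build_sequences(composed_frames, ppg=None, heart_rate: float | None = None
                    ) -> list[SequenceSample]:
    """Chop a composed-frame stream into floor(n/60) sequences."""
    frames = np.asarray(composed_frames, dtype=float)
    n_seq = frames.shape[0] // SEQUENCE_LENGTH
    samples = []
    for k in range(n_seq):
        sl = slice(k * SEQUENCE_LENGTH, (k + 1) * SEQUENCE_LENGTH)
        chunk_ppg = None if ppg is None else np.asarray(ppg, dtype=float)[sl]
        samples.append(SequenceSample(frames[sl], chunk_ppg, heart_rate))
    return samples


@dataclass(frozen=True)
class SplitPlan:
    train_frac: float = 0.88
    test_frac: float = 0.12
    pretrain_frac_of_train: float = 0.22
    query_frac: float = 0.55
    support_frac: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if abs(self.train_frac + self.test_frac - 1.0) > 1e-9:
            raise ConfigurationError("train_frac + test_frac must equal 1")
        if abs(self.query_frac + self.support_frac - 1.0) > 1e-9:
            raise ConfigurationError("query_frac + support_frac must equal 1")


def split_dataset(samples, plan: SplitPlan | None = None) -> dict[str, list]:
    """Seeded, disjoint, exhaustive partition into the four data routes."""
    plan = plan or SplitPlan()
    samples = list(samples)
    n = len(samples)
    if n < 10:
        raise ConfigurationError(f"need at least 10 samples to split, got {n}")
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(n)
    n_train = int(round(plan.train_frac * n))
    n_train = min(max(n_train, 2), n - 1)  # keep both partitions non-empty
    train_idx, test_idx = order[:n_train], order[n_train:]
    n_pre = int(round(plan.pretrain_frac_of_train * n_train))
    n_pre = min(max(n_pre, 2), n_train - 1)
    pre_idx, rest_idx = train_idx[:n_pre], train_idx[n_pre:]
    n_query = min(max(int(round(plan.query_frac * n_pre)), 1), n_pre - 1)
    query_idx, support_idx = pre_idx[:n_query], pre_idx[n_query:]
    return {
        "pretrain_query": [samples[i] for i in query_idx],
        "pretrain_support": [samples[i] for i in support_idx],
        "train": [samples[i] for i in rest_idx],
        "test": [samples[i] for i in test_idx],
    }


def normalize_ppg_sequence(ppg: np.ndarray) -> np.ndarray:
    """Per-sequence min-max normalization to [0, 1]."""
    ppg = np.asarray(ppg, dtype=float)
    span = np.ptp(ppg)
    if span == 0:
        return np.full_like(ppg, 0.5)
    return (ppg - ppg.min()) / span


def ordinal_encode(values: np.ndarray) -> np.ndarray:
    """Cumulative threshold targets: target k is 1 iff value > k/40."""
    values = np.asarray(values, dtype=float)
    thresholds = np.arange(ORDINAL_LEVELS) / ORDINAL_LEVELS
    return (values[..., None] > thresholds).astype(float)


def ordinal_decode(probabilities: np.ndarray) -> np.ndarray:
    """Decoded value = fraction of thresholds with probability > 0.5."""
    probabilities = np.asarray(probabilities, dtype=float)
    return (probabilities > 0.5).sum(axis=-1) / ORDINAL_LEVELS


@dataclass(frozen=True)
class MetaModelConfig:
    channels: int = 3
    lstm_hidden: int = 60  # per direction; bidirectional output is 120
    epochs: int = 10
    pretrain_epochs: int = 2
    learning_rate: float = 1e-3
    adapt_steps: int = 3
    adapt_lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.channels not in (1, 3):
            raise ConfigurationError("channels must be 1 (grayscale) or 3 (RGB)")


class _Conv2DBlock(nn.Module):
    """Conv2D + BatchNorm + AvgPool + ReLU, with a 1x1-projected shortcut."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, rng, pad=1)
        self.bn = nn.BatchNorm(out_ch)
        self.pool = nn.AvgPool2d(2)
        self.shortcut = nn.Conv2d(in_ch, out_ch, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        main = self.pool(self.bn(self.conv(x)))
        skip = self.pool(self.shortcut(x))
        return (main + skip).relu()


class _Conv1DBlock(nn.Module):
    """Temporal resize + Conv1D + BatchNorm + ReLU over 120 channels."""

    def __init__(self, channels: int, out_len: int, rng: np.random.Generator):
        super().__init__()
        self.out_len = out_len
        self.conv = nn.Conv1d(channels, channels, 3, rng, pad=1)
        self.bn = nn.BatchNorm(channels)
        self._resize_cache: dict[int, nn.Tensor] = {}

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        src_len = x.shape[-1]
        if src_len != self.out_len:
            key = src_len
            if key not in self._resize_cache:
                self._resize_cache[key] = nn.Tensor(
                    nn.time_resize_matrix(src_len, self.out_len).T)
            x = x @ self._resize_cache[key]
        return self.bn(self.conv(x)).relu()


class MetaNet(nn.Module):
    """Convolutional encoder + BiLSTM ordinal estimator + gradient generator."""

    def __init__(self, config: MetaModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = (config.channels,) + ENCODER_WIDTHS
        self.encoder_blocks = [
            _Conv2DBlock(widths[i], widths[i + 1], rng) for i in range(5)
        ]
        self.encoder_pool = nn.AvgPool2d(2)
        feat = ENCODER_WIDTHS[-1]
        self.lstm = nn.LSTM(feat, config.lstm_hidden, rng, bidirectional=True)
        self.linear = nn.Linear(2 * config.lstm_hidden, 80, rng)
        self.ordinal = nn.Linear(80, ORDINAL_LEVELS, rng)
        self.generator_blocks = [
            _Conv1DBlock(feat, out_len, rng) for out_len in (40, 20, 40, SEQUENCE_LENGTH)
        ]

    # -- sub-networks --------------------------------------------------
    def encoder_parameters(self) -> list[nn.Tensor]:
        params = []
        for block in self.encoder_blocks:
            params.extend(block.parameters())
        return params

    def estimator_parameters(self) -> list[nn.Tensor]:
        return self.lstm.parameters() + self.linear.parameters() + self.ordinal.parameters()

    def generator_parameters(self) -> list[nn.Tensor]:
        params = []
        for block in self.generator_blocks:
            params.extend(block.parameters())
        return params

    def encode(self, sequences: nn.Tensor, probe: list | None = None) -> nn.Tensor:
        """(N, T, C, 64, 64) -> per-frame feature sequence (N, T, 120)."""
        n, t = sequences.shape[0], sequences.shape[1]
        x = sequences.reshape(n * t, *sequences.shape[2:])
        for block in self.encoder_blocks:
            x = block(x)
            if probe is not None:
                probe.append((t,) + x.shape[1:])
        x = self.encoder_pool(x)  # (N*T, 120, 1, 1)
        x = x.reshape(n, t, ENCODER_WIDTHS[-1])
        if probe is not None:
            probe.append(x.shape[1:])
        return x

    def estimate(self, features: nn.Tensor, probe: list | None = None) -> nn.Tensor:
        """(N, T, 120) -> ordinal logits (N, T, 40)."""
        x = self.lstm(features)
        if probe is not None:
            probe.append(x.shape[1:])
        x = self.linear(x).relu()
        if probe is not None:
            probe.append(x.shape[1:])
        logits = self.ordinal(x)
        if probe is not None:
            probe.append(logits.shape[1:])
        return logits

    def generate_gradient(self, features: nn.Tensor, probe: list | None = None) -> nn.Tensor:
        """(N, T, 120) -> synthetic encoder-feature gradient (N, T, 120)."""
        x = features.transpose(0, 2, 1)  # (N, 120, T)
        for block in self.generator_blocks:
            x = block(x)
            if probe is not None:
                probe.append((x.shape[2], x.shape[1]))
        return x.transpose(0, 2, 1)

    def forward(self, sequences: nn.Tensor) -> nn.Tensor:
        return self.estimate(self.encode(sequences))

    def shape_probe(self) -> dict[str, list]:
        """Intermediate shapes for one 60x64x64xC sequence, eval mode."""
        mode = self.training
        self.eval()
        x = nn.Tensor(np.zeros((1, SEQUENCE_LENGTH, self.config.channels,
                                COMPOSED_SIZE, COMPOSED_SIZE)))
        enc_probe: list = []
        feats = self.encode(x, enc_probe)
        est_probe: list = []
        self.estimate(feats, est_probe)
        gen_probe: list = []
        self.generate_gradient(feats.detach(), gen_probe)
        self.train(mode)
        return {"encoder": enc_probe, "estimator": est_probe, "generator": gen_probe}


def build_meta_network(channels: int = 3, config: MetaModelConfig | None = None) -> MetaNet:
    if config is None:
        config = MetaModelConfig(channels=channels)
    elif config.channels != channels:
        raise ConfigurationError("channels argument disagrees with config.channels")
    return MetaNet(config)


def _to_input(samples: list[SequenceSample]) -> np.ndarray:
    # (N, T, C, H, W), scaled to roughly unit range
    return np.stack([s.frames.transpose(0, 3, 1, 2) for s in samples]) / 255.0


def _ordinal_targets(samples: list[SequenceSample]) -> np.ndarray:
    return np.stack([ordinal_encode(normalize_ppg_sequence(s.ppg)) for s in samples])


def _supervised_step(model: MetaNet, batch: list[SequenceSample],
                     optimizer, train_generator: bool = False,
                     gen_optimizer=None) -> tuple[float, float]:
    x = nn.Tensor(_to_input(batch))
    targets = _ordinal_targets(batch)
    features = model.encode(x)
    logits = model.estimate(features)
    loss = nn.bce_with_logits(logits, targets)
    optimizer.zero_grad()
    if gen_optimizer is not None:
        gen_optimizer.zero_grad()
    loss.backward()
    gen_loss_val = 0.0
    if train_generator:
        true_grad = features.grad.copy()
        predicted = model.generate_gradient(features.detach())
        gen_loss = nn.mse_loss(predicted, true_grad)
        gen_loss.backward()
        gen_loss_val = float(gen_loss.data)
        if gen_optimizer is not None:
            gen_optimizer.step()
    optimizer.step()
    return float(loss.data), gen_loss_val


def train_meta(splits: dict[str, list], config: MetaModelConfig | None = None,
               model: MetaNet | None = None) -> tuple[MetaNet, dict[str, list[float]]]:
    """Two-phase training: episodic pre-training, then supervised training.

    Phase 1 loops over the support partition (adaptation steps updating
    encoder and estimator) and the query partition (evaluation steps
    updating the estimator only).  Phase 2 trains on the train partition
    with the ordinal binary cross-entropy plus the gradient-matching loss
    for the synthetic-gradient generator.
    """
    config = config or MetaModelConfig()
    for name in ("pretrain_query", "pretrain_support", "train", "test"):
        if not splits.get(name):
            raise ConfigurationError(f"empty partition {name!r}")
    model = model or MetaNet(config)
    rng = np.random.default_rng(config.seed)
    opt_main = nn.Adam(model.encoder_parameters() + model.estimator_parameters(),
                       lr=config.learning_rate)
    opt_est = nn.Adam(model.estimator_parameters(), lr=config.learning_rate)
    opt_gen = nn.Adam(model.generator_parameters(), lr=config.learning_rate)
    history: dict[str, list[float]] = {
        "pretrain_support": [], "pretrain_query": [], "train": [], "generator": [],
    }
    model.train()

    for _ in range(config.pretrain_epochs):
        sup_losses, qry_losses = [], []
        support = list(splits["pretrain_support"])
        query = list(splits["pretrain_query"])
        rng.shuffle(support)
        rng.shuffle(query)
        for sample in support:  # adaptation steps
            loss, _ = _supervised_step(model, [sample], opt_main)
            sup_losses.append(loss)
        for sample in query:  # evaluation steps (estimator refinement only)
            loss, _ = _supervised_step(model, [sample], opt_est)
            qry_losses.append(loss)
        history["pretrain_support"].append(float(np.mean(sup_losses)))
        history["pretrain_query"].append(float(np.mean(qry_losses)))

    for _ in range(config.epochs):
        train_set = list(splits["train"])
        rng.shuffle(train_set)
        losses, gen_losses = [], []
        for sample in train_set:
            loss, gen_loss = _supervised_step(model, [sample], opt_main,
                                              train_generator=True,
                                              gen_optimizer=opt_gen)
            losses.append(loss)
            gen_losses.append(gen_loss)
        history["train"].append(float(np.mean(losses)))
        history["generator"].append(float(np.mean(gen_losses)))
    model.eval()
    return model, history


def adapt_and_predict(model: MetaNet, sequences: list[SequenceSample],
                      adapt_steps: int | None = None, fps: float = 30.0,
                      window_s: float = 10.0) -> tuple[PpgTrace, "BpmSeries"]:
    """Transductive inference on unlabeled sequences.

    Performs ``adapt_steps`` encoder updates driven by generator-produced
    gradients (0 = pure inference), then decodes the ordinal outputs into a
    PPG trace and converts it to BPM.
    """
    config = model.config
    k = config.adapt_steps if adapt_steps is None else adapt_steps
    x_data = _to_input(sequences)
    if k > 0:
        saved = [p.data.copy() for p in model.parameters()]
        model.train()
        sgd = nn.SGD(model.encoder_parameters(), lr=config.adapt_lr)
        for _ in range(k):
            sgd.zero_grad()
            for i in range(x_data.shape[0]):  # one sequence at a time
                features = model.encode(nn.Tensor(x_data[i : i + 1]))
                with nn.no_grad():
                    pseudo_grad = model.generate_gradient(features.detach()).data
                surrogate = (features * nn.Tensor(pseudo_grad)).sum()
                surrogate.backward()
            sgd.step()
    model.eval()
    with nn.no_grad():
        logits = np.concatenate(
            [model(nn.Tensor(x_data[i : i + 1])).data for i in range(x_data.shape[0])])
    probs = 1.0 / (1.0 + np.exp(-logits))
    decoded = ordinal_decode(probs)  # (N, 60)
    trace = PpgTrace(samples=decoded.reshape(-1), fs=fps)
    if k > 0:  # restore pre-adaptation weights; adaptation is per-call
        for p, data in zip(model.parameters(), saved):
            p.data[...] = data
    window_s = min(window_s, trace.duration)
    bpm = ppg_to_bpm(trace, window_s=window_s)
    return trace, bpm
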