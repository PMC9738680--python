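import numpy as np
import pytest

from hmdpulse import evm, nn
from hmdpulse.errors import ConfigurationError, WindowingError
from hmdpulse.hr_signal import PpgTrace
from hmdpulse.synth import pulse_waveform

FPS = 30.0


def pulsing_roi_stream(hr, n_frames, phase=0.0, amp=10.0, size=24, fps=FPS):
    """Uniform skin-colored ROI frames modulated by the pulse waveform."""
    t = np.arange(n_frames) / fps
    w = pulse_waveform(2 * np.pi * (hr / 60.0) * t + phase)
    base = np.array([198.0, 144.0, 122.0])
    frames = base[None, None, None, :] + amp * w[:, None, None, None]
    return np.clip(np.rint(frames), 0, 255).astype(np.uint8) * np.ones(
        (1, size, size, 1), dtype=np.uint8)


class TestLabelNormalization:
    def test_45_maps_to_zero(self):
        assert evm.normalize_bpm(45.0) == 0.0

    def test_240_maps_to_one(self):
        assert evm.normalize_bpm(240.0) == 1.0

    def test_midpoint(self):
        assert evm.normalize_bpm(142.5) == pytest.approx(0.5)

    def test_roundtrip_exact(self):
        bpms = np.linspace(45, 240, 53)
        np.testing.assert_allclose(evm.denormalize_bpm(evm.normalize_bpm(bpms)),
                                   bpms, rtol=1e-12)

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert evm.normalize_bpm(20.0) == 0.0


class TestSpatialLowestBand:
    def test_constant_frame(self):
        out = evm.spatial_lowest_band(np.full((100, 100, 3), 37.0))
        assert out.shape == (5, 5, 3)
        np.testing.assert_allclose(out, 37.0, rtol=1e-6)

    def test_level_count_oracle(self):
        # 100 -> 50 -> 25 -> 13 -> 7 (stop at <= 8), then resize to 5
        sizes = [100]
        while min(sizes[-1], sizes[-1]) > 8:
            sizes.append(int(np.ceil(sizes[-1] / 2)))
        assert sizes == [100, 50, 25, 13, 7]
        out = evm.spatial_lowest_band(np.zeros((100, 100, 3)))
        assert out.shape == (5, 5, 3)

    def test_horizontal_ramp_monotone(self):
        ramp = np.tile(np.linspace(0, 255, 64), (64, 1))[..., None].repeat(3, -1)
        out = evm.spatial_lowest_band(ramp)
        # rows equal, columns increasing
        np.testing.assert_allclose(out[0, :, 0], out[3, :, 0], atol=1e-6)
        assert np.all(np.diff(out[2, :, 0]) > 0)


class TestBandpassRows:
    def test_idempotent(self, rng):
        rows = rng.normal(size=(25, 3, 25))
        once = evm.bandpass_rows(rows, fs=25.0)
        twice = evm.bandpass_rows(once, fs=25.0)
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_band_energy_bookkeeping(self):
        # 0.2 Hz drift + 2 Hz tone over 10 s at 0.1 Hz resolution
        fs, dur = 30.0, 10.0
        t = np.arange(0, dur, 1 / fs)
        signal = 5.0 * np.sin(2 * np.pi * 0.2 * t) + 1.0 * np.sin(2 * np.pi * 2.0 * t)
        out = evm.bandpass_rows(signal[None, :], fs=fs)[0]
        spectrum = np.abs(np.fft.rfft(out)) ** 2
        freqs = np.fft.rfftfreq(t.size, 1 / fs)
        in_band = (freqs >= 0.75) & (freqs <= 4.0)
        assert spectrum[~in_band].sum() <= 0.01 * spectrum[in_band].sum()

    def test_6hz_removed(self):
        fs = 30.0
        t = np.arange(0, 10, 1 / fs)
        out = evm.bandpass_rows(np.sin(2 * np.pi * 6.0 * t)[None, :], fs=fs)[0]
        assert np.abs(out).max() < 1e-9


class TestFeatureImage:
    def test_constant_video_all_zero(self):
        frames = [np.full((100, 100, 3), 120.0)] * 30
        fi = evm.build_feature_image(frames, FPS)
        np.testing.assert_allclose(fi.data, 0.0, atol=1e-10)

    def test_2hz_tone_dominant_bin(self):
        t = np.arange(30) / FPS
        frames = [np.full((64, 64, 3), 120.0 + 10 * np.sin(2 * np.pi * 2.0 * tt))
                  for tt in t]
        fi = evm.build_feature_image(frames, FPS)
        for row in range(25):
            spectrum = np.abs(np.fft.rfft(fi.data[row, :, 1]))
            assert np.argmax(spectrum[1:]) + 1 == 2  # 1 Hz bins -> bin 2 is 2 Hz

    def test_too_short_window_raises(self):
        frames = [np.zeros((32, 32, 3))] * 10
        with pytest.raises(WindowingError):
            evm.build_feature_image(frames, FPS)

    def test_shape_contract(self):
        with pytest.raises(ValueError):
            evm.FeatureImage(np.zeros((25, 24, 3)))


class TestNetwork:
    def test_first_conv_parameter_count(self):
        model = evm.build_evm_network()
        assert model.conv_layers[0].weight.data.size == 5 * 5 * 3 * 96

    def test_forward_scalar_output(self):
        model = evm.build_evm_network()
        model.eval()
        out = model(nn.Tensor(np.zeros((1, 3, 25, 25))))
        assert out.shape == (1, 1)

    def test_table_shape_trace(self):
        probe = evm.build_evm_network().shape_probe()
        spatial = [p[2] for p in probe if len(p) == 4]
        assert spatial == [23, 21, 21, 11, 11, 6, 6, 3, 3, 2, 2, 1]
        assert probe[-2] == (1, 192)
        assert probe[-1] == (1, 1)

    def test_dropout_ratio(self):
        model = evm.build_evm_network()
        assert model.dropout.p == 0.6

    def test_seeded_builds_identical(self):
        a = evm.build_evm_network(evm.EvmModelConfig(seed=3))
        b = evm.build_evm_network(evm.EvmModelConfig(seed=3))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_ppg_head_width(self):
        model = evm.build_evm_network(evm.EvmModelConfig(target="ppg"))
        out = model(nn.Tensor(np.zeros((2, 3, 25, 25))))
        assert out.shape == (2, 25)


def small_training_set(n_clips=8, windows_per_clip=4, seed=0):
    rng = np.random.default_rng(seed)
    data = []
    for hr in rng.uniform(60, 120, n_clips):
        frames = pulsing_roi_stream(hr, 30 * (windows_per_clip + 1),
                                    phase=rng.uniform(0, 2 * np.pi))
        for start, stop in evm.sliding_windows(len(frames), FPS):
            fi = evm.build_feature_image(frames[start:stop], FPS, start)
            data.append((fi, evm.normalize_bpm(hr)))
    return data


class TestTraining:
    def test_loss_decreases(self):
        data = small_training_set()
        config = evm.EvmModelConfig(epochs=8, batch_size=8, learning_rate=2e-3, seed=0)
        _, history = evm.train_evm(data, config)
        assert history[-1] < history[0]

    def test_constant_labels_converge(self):
        # degenerate regression; dropout off and lr stepped down so the
        # L1-type loss settles instead of oscillating around the constant
        data = [(fi, 0.4) for fi, _ in small_training_set(n_clips=2)]
        model, _ = evm.train_evm(data, evm.EvmModelConfig(
            epochs=60, batch_size=10, learning_rate=1e-2, dropout=0.0, seed=0))
        model, _ = evm.train_evm(data, evm.EvmModelConfig(
            epochs=20, batch_size=10, learning_rate=1e-3, dropout=0.0, seed=1),
            model=model)
        preds = model(nn.Tensor(np.stack(
            [f.data.transpose(2, 0, 1) for f, _ in data]))).data
        assert np.abs(preds - 0.4).mean() < 0.1

    def test_empty_dataset_raises(self):
        with pytest.raises(ConfigurationError):
            evm.train_evm([], evm.EvmModelConfig())

    def test_seeded_training_reproducible(self):
        data = small_training_set(n_clips=3)
        config = evm.EvmModelConfig(epochs=2, batch_size=8, seed=1)
        _, h1 = evm.train_evm(data, config)
        _, h2 = evm.train_evm(data, config)
        assert h1 == h2


class TestPredict:
    def test_constant_input_constant_prediction(self):
        model = evm.build_evm_network()
        frames = np.full((90, 32, 32, 3), 120, dtype=np.uint8)
        _, bpm = evm.predict_evm(model, frames, FPS)
        assert np.allclose(bpm, bpm[0])

    def test_window_count(self):
        model = evm.build_evm_network()
        frames = pulsing_roi_stream(72.0, 30 * 5)  # 5 seconds
        times, bpm = evm.predict_evm(model, frames, FPS)
        assert len(bpm) == 5  # stride 1 s, non-overlapping

    def test_ppg_target_output_length(self):
        model = evm.build_evm_network(evm.EvmModelConfig(target="ppg"))
        frames = pulsing_roi_stream(72.0, 30 * 4)
        trace = evm.predict_evm(model, frames, FPS)
        assert isinstance(trace, PpgTrace)
        assert trace.samples.size == 25 * 4

    def test_too_short_stream_raises(self):
        model = evm.build_evm_network()
        with pytest.raises(WindowingError):
            evm.predict_evm(model, np.zeros((10, 16, 16, 3)), FPS)
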