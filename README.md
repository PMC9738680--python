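# hmdpulse

Remote heart-rate estimation from facial regions visible to head-mounted-display
(HMD) cameras — the two eye regions and the lower face — exercised end to end on
synthetic pulse-bearing face videos.

The package implements:

- **`hmdpulse.synth`** — synthetic face-video generator: an ellipsoidal skin
  region whose color is modulated by a pulse waveform at a known heart rate,
  with ground-truth landmarks, head-translation jitter, noise and a
  ground-truth PPG trace (UBFC-style export).
- **`hmdpulse.roi`** — stabilized ROI extractor: landmark-group centers,
  a movement threshold of 5% of the ROI side (jitter below the threshold is
  ignored; motion above it updates the center by replacement or averaging),
  100×100 eye crops, a 400×400 lower-face crop with a radial
  ("approximation") mouth distortion, PNG/PGM export and a CSV track log.
- **`hmdpulse.magnify`** — optional causal Eulerian motion magnification
  (Gaussian pyramid + causal one-pole IIR band-pass; no future frames).
- **`hmdpulse.evm`** — 25×25×3 feature images (lowest Gaussian-pyramid band
  per frame, one-second windows, 0.75–4 Hz FFT band-pass per pixel row) and
  the depthwise-separable regression CNN (96-96-96-128-128, dropout 0.6,
  Euclidean loss, Adam), with BPM-target (labels affinely normalized,
  45 BPM → 0, 240 BPM → 1) and PPG-target variants.
- **`hmdpulse.meta`** — 64×64 composed-frame estimator: five-block
  convolutional encoder with shortcut connections, bidirectional LSTM,
  ordinal 40-threshold output, Conv1D synthetic-gradient generator for
  transductive adaptation on unlabeled sequences, and the 88/12 train/test
  split with 22% of training routed to few-shot pre-training (55/45
  query/support).
- **`hmdpulse.hr_signal`** — 30 FPS rescaling, PPG filtering, adaptive peak
  detection and PPG→BPM conversion.
- **`hmdpulse.metrics`** — ME, SD, RMSE, MAPE (percent) and Pearson ρ.
- **`hmdpulse.pipeline` / `hmdpulse.cli`** — configuration and end-to-end
  orchestration.
- **`hmdpulse.nn`** — a small numpy autodiff/NN backend (conv2d, depthwise
  conv, conv1d, batch norm, LSTM, Adam, …) used by both estimators, so the
  package has no deep-learning framework dependency.

## CLI

```bash
hmdpulse simulate --out clip/ --duration 4 --heart-rate 72      # synthetic clip
hmdpulse extract --frames-dir clip/ --out rois/                 # stabilized ROIs
hmdpulse magnify --frames-dir clip/ --out magnified/ --alpha 10
hmdpulse evm-train --frames-dir rois/left_eye --truth clip/ground_truth.txt \
    --checkpoint evm.npz
hmdpulse evm-predict --frames-dir rois/left_eye --checkpoint evm.npz --out pred.csv
hmdpulse meta-train --roi-root rois/ --truth clip/ground_truth.txt \
    --checkpoint meta.npz
hmdpulse meta-predict --roi-root rois/ --checkpoint meta.npz --out ppg.txt
hmdpulse ppg2bpm trace.txt --fs 30
hmdpulse evaluate pred.csv truth.csv
hmdpulse run --model evm --heart-rate 72 --duration 4 --out result.json
```

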