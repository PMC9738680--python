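"""Frame-directory, trace and checkpoint I/O.

Ground-truth traces use the UBFC-style whitespace-delimited text layout:
line 1 PPG samples, line 2 BPM samples, line 3 timestamps.
"""

from __future__ import annotations

import json
import os
import re

import numpy as np
from PIL import Image

__all__ = [
    "read_ubfc_trace", "write_ubfc_trace",
    "read_frames_dir", "write_frames_dir", "iter_frames",
    "save_checkpoint", "load_checkpoint",
]

_FRAME_RE = re.compile(r"(\d+)\.(png|pgm|ppm|jpg|jpeg|bmp|tif|tiff)$", re.IGNORECASE)


def read_ubfc_trace(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read (ppg, bpm, timestamps) from a UBFC-style text file."""
    with open(path) as fh:
        lines = [line for line in fh.read().splitlines() if line.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: expected 3 non-empty lines, found {len(lines)}")
    ppg, bpm, ts = (np.array([float(v) for v in line.split()]) for line in lines[:3])
    return ppg, bpm, ts


def write_ubfc_trace(path: str, ppg, bpm, timestamps):
    rows = [np.asarray(x, dtype=float).ravel() for x in (ppg, bpm, timestamps)]
    with open(path, "w") as fh:
        for row in rows:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def _frame_paths(directory: str) -> list[str]:
    entries = []
    for name in os.listdir(directory):
        match = _FRAME_RE.search(name)
        if match:
            entries.append((int(match.group(1)), name))
    if not entries:
        raise FileNotFoundError(f"no numbered frames found in {directory}")
    entries.sort()
    return [os.path.join(directory, name) for _, name in entries]


def iter_frames(directory: str):
    """Yield frames from a directory of numbered images, in index order."""
    for path in _frame_paths(directory):
        yield np.asarray(Image.open(path))


def read_frames_dir(directory: str) -> np.ndarray:
    return np.stack(list(iter_frames(directory)))


def write_frames_dir(frames, directory: str, prefix: str = "frame"):
    os.makedirs(directory, exist_ok=True)
    for i, frame in enumerate(frames):
        arr = np.asarray(frame)
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        ext = "pgm" if arr.ndim == 2 else "png"
        mode = "L" if arr.ndim == 2 else "RGB"
        Image.fromarray(arr, mode=mode).save(
            os.path.join(directory, f"{prefix}_{i:06d}.{ext}"))


def save_checkpoint(path: str, state: dict, meta: dict):
    """Model checkpoint: npz of arrays plus an embedded JSON metadata blob."""
    payload = dict(state)
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path: str) -> tuple[dict, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    return state, meta
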