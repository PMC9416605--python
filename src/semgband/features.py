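"""FFT-magnitude feature extraction for gesture classification.

Two representations of each 4 x 13,000-sample movement segment are supported:

* the *full* half spectrum — per sensor the first 6,500 magnitudes of the
  13,000-point DFT (bin resolution 1000/13000 ~= 0.0769 Hz) with the first
  five positions zeroed, as they carry the DC-region components that hold no
  movement information; sensors concatenated give 26,000 values per instance;
* the *average-of-sequences* vector — per sensor 50 values, each the mean of
  the DFT magnitudes over one ~10 Hz band.  Bin i (i = 1..50) averages
  transform positions 5+130(i-1) .. 130*i inclusive (0-based), i.e. 126
  magnitudes per bin with four positions skipped at each bin boundary and the
  five DC-region positions skipped ahead of bin 1; bin 50 ends at position
  6,500.  ``clean_bins=True`` instead averages contiguous 130-wide bins (DC
  positions zeroed) for users who consider the boundary gap an artifact of
  the binning rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import MovementSegment, TARGET_SAMPLES

HALF_SPECTRUM = TARGET_SAMPLES // 2  # 6500
N_DC_BINS = 5
N_AVG_BINS = 50
BIN_STRIDE = 130
SENSORS = 4
FULL_FEATURES = SENSORS * HALF_SPECTRUM      # 26,000 per instance
AVG_FEATURES = SENSORS * N_AVG_BINS          # 200 per instance


def _check_length(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != TARGET_SAMPLES:
        raise ValueError(f"expected {TARGET_SAMPLES} samples, got {x.shape[-1]}; "
                         "segments are not resampled implicitly")
    return x


def half_spectrum(samples) -> np.ndarray:
    """First 6,500 DFT magnitudes of one sensor with the 5 DC-region bins zeroed."""
    x = _check_length(samples)
    mag = np.abs(np.fft.rfft(x))[..., :HALF_SPECTRUM]
    mag[..., :N_DC_BINS] = 0.0
    return mag


def full_fft_features(segment) -> np.ndarray:
    """Full-spectrum feature vector: 4 half spectra concatenated (26,000 values)."""
    samples = segment.samples if isinstance(segment, MovementSegment) else np.asarray(segment)
    if samples.shape[0] != SENSORS:
        raise ValueError(f"expected {SENSORS} sensor rows, got {samples.shape[0]}")
    return half_spectrum(samples).reshape(-1)


def fft_avg_sequences(sensor_samples, clean_bins: bool = False) -> np.ndarray:
    """Average-of-sequences vector of one sensor: 50 per-band mean magnitudes.

    Default mode: bin i (0-based here) is the mean of the 0-based transform
    positions ``5+130i .. 130(i+1)`` inclusive — 126 values per bin, the last
    bin ending at position 6,500.
    """
    x = _check_length(np.asarray(sensor_samples, dtype=float).ravel())
    mag = np.abs(np.fft.fft(x))
    if clean_bins:
        mag = mag.copy()
        mag[:N_DC_BINS] = 0.0
        return mag[: N_AVG_BINS * BIN_STRIDE].reshape(N_AVG_BINS, BIN_STRIDE).mean(axis=1)
    starts = N_DC_BINS + BIN_STRIDE * np.arange(N_AVG_BINS)
    idx = starts[:, None] + np.arange(BIN_STRIDE - N_DC_BINS + 1)
    return mag[idx].mean(axis=1)


def avg_fft_features(segment, clean_bins: bool = False) -> np.ndarray:
    """Average-of-sequences feature vector over the 4 sensors (200 values)."""
    samples = segment.samples if isinstance(segment, MovementSegment) else np.asarray(segment)
    if samples.shape[0] != SENSORS:
        raise ValueError(f"expected {SENSORS} sensor rows, got {samples.shape[0]}")
    return np.concatenate([fft_avg_sequences(row, clean_bins=clean_bins) for row in samples])


@dataclass
class DatasetMatrix:
    """Stacked feature vectors with one-hot labels and instance metadata."""

    X: np.ndarray
    Y: np.ndarray
    metadata: pd.DataFrame
    class_names: tuple
    mode: str

    @property
    def y(self) -> np.ndarray:
        """Integer class labels (argmax of the one-hot rows)."""
        return np.argmax(self.Y, axis=1)

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def save(self, outdir) -> Path:
        """Write X/metadata as delimited text plus a JSON sidecar; returns the dir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "X.csv", self.X, fmt="%.8g", delimiter=",")
        self.metadata.to_csv(outdir / "instances.csv", index=False)
        with open(outdir / "dataset.json", "w") as fh:
            json.dump({"mode": self.mode, "class_names": list(self.class_names),
                       "shape": list(self.X.shape)}, fh)
        return outdir

    @classmethod
    def load(cls, directory) -> "DatasetMatrix":
        directory = Path(directory)
        with open(directory / "dataset.json") as fh:
            meta = json.load(fh)
        X = np.loadtxt(directory / "X.csv", delimiter=",", ndmin=2)
        table = pd.read_csv(directory / "instances.csv")
        class_names = tuple(meta["class_names"])
        y = np.array([class_names.index(m) for m in table["movement"]])
        Y = np.eye(len(class_names))[y]
        return cls(X, Y, table, class_names, meta["mode"])


def assemble_matrix(segments, mode: str = "average", clean_bins: bool = False) -> DatasetMatrix:
    """Stack per-segment feature vectors into the classifier input matrix.

    Rows are ordered deterministically by (subject, arm, cycle, movement);
    labels are one-hot over the movement classes present.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments to assemble")
    shapes = {seg.samples.shape for seg in segments}
    if len(shapes) != 1:
        raise ValueError(f"mixed segment shapes {sorted(shapes)}; homogenize first")
    if mode not in ("full", "average"):
        raise ValueError(f"unknown feature mode {mode!r}; use 'full' or 'average'")

    class_names = tuple(sorted({seg.movement for seg in segments}))
    ordered = sorted(segments,
                     key=lambda s: (s.subject_id, s.arm, s.cycle, class_names.index(s.movement)))
    if mode == "full":
        X = np.vstack([full_fft_features(seg) for seg in ordered])
    else:
        X = np.vstack([avg_fft_features(seg, clean_bins=clean_bins) for seg in ordered])
    y = np.array([class_names.index(seg.movement) for seg in ordered])
    Y = np.eye(len(class_names))[y]
    metadata = pd.DataFrame({
        "subject": [s.subject_id for s in ordered],
        "arm": [s.arm for s in ordered],
        "cycle": [s.cycle for s in ordered],
        "movement": [s.movement for s in ordered],
    })
    return DatasetMatrix(X, Y, metadata, class_names, mode)
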