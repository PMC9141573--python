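"""Deterministic EEG-epoch → spectrogram-image preprocessing.

Every 30-s epoch, whatever its source rate, is turned into a fixed
76×60×3 RGB image:

1. resample to 64 Hz (1920 samples; Nyquist 32 Hz covers every scoring band),
2. short-time Fourier transform — Hann window 256, hop 128 → 129 bins × 14
   frames of power in dB (floor −120 dB),
3. rasterize — per-image min–max normalisation to [0,1], bilinear resize to a
   100-row (frequency, row 0 = 32 Hz) × 80-column (time) dot grid, colormap
   lookup against a bundled 256-entry viridis-style RGB table,
4. crop rows [14,90) and columns [11,71) → 76×60×3.

The raster replaces a plotting-library canvas with a direct, deterministic
rendering that preserves the published geometry (100×80 dots, 0–32 Hz,
identical crop box).  Log power followed by per-image min–max normalisation
makes the result invariant to any positive rescaling of the input signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import gcd

import numpy as np
from scipy import signal as sps

from .signal_io import SleepEpoch

__all__ = [
    "TARGET_RATE",
    "EPOCH_SAMPLES_64",
    "STFT_WINDOW",
    "STFT_HOP",
    "RASTER_ROWS",
    "RASTER_COLS",
    "CROP_ROWS",
    "CROP_COLS",
    "IMAGE_SHAPE",
    "DB_FLOOR",
    "StftGrid",
    "SpectrogramImage",
    "resample_to_64",
    "stft_power",
    "rasterize",
    "crop",
    "epoch_to_image",
    "frequency_of_cropped_row",
    "frame_time_of_cropped_col",
    "viridis_lut",
]

TARGET_RATE = 64
EPOCH_SAMPLES_64 = 30 * TARGET_RATE  # 1920
STFT_WINDOW = 256
STFT_HOP = 128
DB_FLOOR = -120.0
MAX_FREQ = 32.0  # Hz; Nyquist at 64 Hz

RASTER_ROWS = 100  # frequency axis, row 0 = 32 Hz
RASTER_COLS = 80  # time axis
CROP_ROWS = (14, 90)  # half-open [14, 90) -> 76 rows
CROP_COLS = (11, 71)  # half-open [11, 71) -> 60 cols
IMAGE_SHAPE = (76, 60, 3)


@dataclass
class StftGrid:
    """Power grid of 129 frequency bins (0–32 Hz, 0.25 Hz apart) × 14 frames, dB."""

    power: np.ndarray  # (129, T) dB
    bin_hz: float
    frame_hop_s: float


@dataclass
class SpectrogramImage:
    """The 76×60×3 cropped, colormapped time-frequency image fed to the model."""

    pixels: np.ndarray  # (76, 60, 3) in [0, 1]
    epoch_ref: tuple[str, int] | None = None


_LUT_CACHE: np.ndarray | None = None


def viridis_lut() -> np.ndarray:
    """The bundled 256×3 RGB lookup table (values in [0, 1])."""
    global _LUT_CACHE
    if _LUT_CACHE is None:
        text = resources.files("eegsnet.data").joinpath("viridis_lut.csv").read_text()
        rows = [
            [float(v) for v in line.split(",")]
            for line in text.splitlines()
            if line and not line.startswith("#")
        ]
        _LUT_CACHE = np.asarray(rows, dtype=np.float64)
        assert _LUT_CACHE.shape == (256, 3)
    return _LUT_CACHE


def resample_to_64(samples: np.ndarray, src_rate: float) -> np.ndarray:
    """Resample a 30-s signal to 64 Hz (polyphase, anti-aliased).

    Only the downsampling path is supported: rates below 64 Hz are rejected.
    """
    samples = np.asarray(samples, dtype=np.float64).ravel()
    if src_rate < TARGET_RATE:
        raise ValueError(
            f"unsupported sample rate {src_rate} Hz: resampling targets "
            f"{TARGET_RATE} Hz and upsampling is not supported"
        )
    expect = int(round(30 * src_rate))
    if len(samples) != expect:
        raise ValueError(
            f"expected {expect} samples (30 s at {src_rate} Hz), got {len(samples)}"
        )
    if src_rate == TARGET_RATE:
        return samples.copy()
    if abs(src_rate - round(src_rate)) > 1e-9:
        raise ValueError(f"non-integer sample rate {src_rate} Hz is not supported")
    src = int(round(src_rate))
    g = gcd(TARGET_RATE, src)
    out = sps.resample_poly(samples, TARGET_RATE // g, src // g)
    if len(out) != EPOCH_SAMPLES_64:  # pragma: no cover - defensive
        out = out[:EPOCH_SAMPLES_64]
    return out


def stft_power(samples_64: np.ndarray) -> StftGrid:
    """One-sided STFT power of a 1920-sample (30 s at 64 Hz) signal in dB.

    Hann window of 256 samples, hop 128, no edge padding:
    floor((1920−256)/128)+1 = 14 frames × 129 bins.  Power is the one-sided
    spectral density; values are clamped at −120 dB.
    """
    x = np.asarray(samples_64, dtype=np.float64).ravel()
    if len(x) != EPOCH_SAMPLES_64:
        raise ValueError(f"expected {EPOCH_SAMPLES_64} samples, got {len(x)}")
    freqs, _, sxx = sps.spectrogram(
        x,
        fs=float(TARGET_RATE),
        window="hann",
        nperseg=STFT_WINDOW,
        noverlap=STFT_WINDOW - STFT_HOP,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    assert sxx.shape == (STFT_WINDOW // 2 + 1, (len(x) - STFT_WINDOW) // STFT_HOP + 1)
    db = 10.0 * np.log10(np.maximum(sxx, 10.0 ** (DB_FLOOR / 10.0)))
    return StftGrid(
        power=db,
        bin_hz=float(freqs[1] - freqs[0]),
        frame_hop_s=STFT_HOP / TARGET_RATE,
    )


def _bilinear_resize(grid: np.ndarray, out_rows: int, out_cols: int) -> np.ndarray:
    """Separable bilinear resize with endpoint-aligned pixel mapping."""
    in_rows, in_cols = grid.shape
    r_src = np.linspace(0.0, in_rows - 1.0, out_rows)
    c_src = np.linspace(0.0, in_cols - 1.0, out_cols)
    tmp = np.empty((out_rows, in_cols))
    for j in range(in_cols):
        tmp[:, j] = np.interp(r_src, np.arange(in_rows), grid[:, j])
    out = np.empty((out_rows, out_cols))
    for i in range(out_rows):
        out[i, :] = np.interp(c_src, np.arange(in_cols), tmp[i, :])
    return out


def rasterize(grid: StftGrid, grayscale: bool = False) -> np.ndarray:
    """Render an :class:`StftGrid` to the 100×80-dot RGB raster.

    Per-image min–max normalisation of the dB values to [0,1], bilinear resize
    of the 129×14 grid to 100 frequency rows × 80 time columns with the
    frequency axis flipped so row 0 is 32 Hz (figure orientation), then RGB
    lookup in the bundled viridis table.  A degenerate all-equal grid maps
    every pixel to colormap entry 0.
    """
    db = np.asarray(grid.power, dtype=np.float64)
    lo, hi = db.min(), db.max()
    norm = np.zeros_like(db) if hi == lo else (db - lo) / (hi - lo)
    resized = _bilinear_resize(norm, RASTER_ROWS, RASTER_COLS)
    resized = resized[::-1, :]  # row 0 = highest frequency (32 Hz)
    if grayscale:
        return np.repeat(resized[:, :, None], 3, axis=2)
    idx = np.clip(np.round(resized * 255).astype(int), 0, 255)
    return viridis_lut()[idx]


def crop(image: np.ndarray) -> np.ndarray:
    """Crop the 100×80×3 raster to the 76×60×3 model input.

    Retains rows [14, 90) (frequency) and columns [11, 71) (time), removing
    the canvas margins of the original rendering geometry.
    """
    image = np.asarray(image)
    if image.shape != (RASTER_ROWS, RASTER_COLS, 3):
        raise ValueError(
            f"expected raster of shape {(RASTER_ROWS, RASTER_COLS, 3)}, "
            f"got {image.shape}"
        )
    r0, r1 = CROP_ROWS
    c0, c1 = CROP_COLS
    return image[r0:r1, c0:c1, :]


def epoch_to_image(epoch: SleepEpoch, grayscale: bool = False) -> SpectrogramImage:
    """Full preprocessing chain: resample → STFT → rasterize → crop."""
    x64 = resample_to_64(epoch.samples, epoch.sample_rate)
    img = crop(rasterize(stft_power(x64), grayscale=grayscale))
    return SpectrogramImage(pixels=img, epoch_ref=(epoch.subject_id, epoch.epoch_index))


# ---------------------------------------------------------------------------
# Geometry helpers: invert the resize + flip + crop so tests (and users) can
# ask which frequency / time a given image pixel represents.
# ---------------------------------------------------------------------------

def frequency_of_cropped_row(row: int) -> float:
    """Centre frequency (Hz) represented by row ``row`` of the 76-row image."""
    if not 0 <= row < CROP_ROWS[1] - CROP_ROWS[0]:
        raise ValueError(f"row {row} outside [0, 76)")
    raster_row = row + CROP_ROWS[0]
    # raster row r (before flip: 99-r) maps linearly onto bins 0..128
    bin_pos = (RASTER_ROWS - 1 - raster_row) * 128.0 / (RASTER_ROWS - 1)
    return bin_pos * 0.25


def frame_time_of_cropped_col(col: int) -> float:
    """Centre time (s) of the STFT frame represented by image column ``col``."""
    if not 0 <= col < CROP_COLS[1] - CROP_COLS[0]:
        raise ValueError(f"col {col} outside [0, 60)")
    raster_col = col + CROP_COLS[0]
    frame_pos = raster_col * 13.0 / (RASTER_COLS - 1)
    return frame_pos * (STFT_HOP / TARGET_RATE) + STFT_WINDOW / (2 * TARGET_RATE)
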