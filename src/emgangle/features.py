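"""Windowing and the three per-channel sEMG features (time, frequency,
time-frequency domains).

Each 250 ms analysis window of each channel is reduced to three scalars:

* MAV — mean absolute value, (1/N) * sum |x(n)|, the standard EMG amplitude
  feature;
* DFT feature — the in-band (20-200 Hz) spectral centroid of the Hann-tapered
  magnitude-squared spectrum, in Hz;
* WT feature — log(1 + energy) of the detail coefficients at one level of a
  discrete wavelet decomposition (db4, level 3 by default).

With the default five-muscle channel map this yields the 15-dimensional
feature vector consumed by the angle regressor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .signal_core import EmgRecording

__all__ = [
    "WindowingSpec",
    "WaveletSpec",
    "FeatureMatrix",
    "FEATURE_KINDS",
    "window_signal",
    "mav",
    "dft",
    "idft",
    "dft_feature",
    "wt_feature",
    "extract_features",
]

logger = logging.getLogger(__name__)

FEATURE_KINDS: tuple[str, ...] = ("mav", "dft", "wt")

DEFAULT_DFT_BAND: tuple[float, float] = (20.0, 200.0)


@dataclass(frozen=True)
class WindowingSpec:
    """Sliding-window parameters (milliseconds)."""

    window_ms: float = 250.0
    stride_ms: float = 125.0

    def __post_init__(self) -> None:
        if not 0 < self.stride_ms <= self.window_ms:
            raise ValueError("need 0 < stride_ms <= window_ms")

    def window_samples(self, sample_rate: float) -> int:
        n = round(self.window_ms * sample_rate / 1000.0)
        if n < 2:
            raise ValueError("window shorter than 2 samples at this rate")
        return n

    def stride_samples(self, sample_rate: float) -> int:
        return max(1, round(self.stride_ms * sample_rate / 1000.0))


@dataclass(frozen=True)
class WaveletSpec:
    """Discrete wavelet decomposition used for the time-frequency feature."""

    wavelet: str = "db4"
    level: int = 3

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-window feature vectors aligned to window centers (seconds)."""

    window_centers: np.ndarray
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        centers = np.asarray(self.window_centers, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "window_centers", centers)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if values.ndim != 2:
            raise ValueError("values must be 2-D (window x feature)")
        if values.shape[0] != centers.size:
            raise ValueError("one window center per feature row required")
        if values.shape[1] != len(self.feature_names):
            raise ValueError("one name per feature column required")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def window_signal(
    rec: EmgRecording, spec: WindowingSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Slice a recording into fixed-length windows.

    Returns ``(windows, centers)`` where ``windows`` has shape
    ``(n_windows, window_samples, n_channels)`` and ``centers`` gives each
    window's mid-time in seconds.  A trailing partial window is dropped.
    """
    spec = spec or WindowingSpec()
    win = spec.window_samples(rec.sample_rate)
    stride = spec.stride_samples(rec.sample_rate)
    n = rec.n_samples
    if n < win:
        raise ValueError(
            f"recording of {n} samples is shorter than one {win}-sample window"
        )
    starts = np.arange(0, n - win + 1, stride)
    windows = np.stack([rec.samples[s : s + win] for s in starts])
    centers = rec.start_time + (starts + (win - 1) / 2.0) / rec.sample_rate
    return windows, centers


def mav(x: np.ndarray) -> float:
    """Mean absolute value of a sample vector."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mav of an empty vector is undefined")
    return float(np.mean(np.abs(x)))


def dft(x: np.ndarray) -> np.ndarray:
    """Discrete Fourier transform X(k) = sum_n x(n) exp(-2i*pi*n*k/N)."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("dft of an empty vector is undefined")
    return np.fft.fft(x)


def idft(X: np.ndarray) -> np.ndarray:
    """Inverse transform x(n) = (1/N) sum_k X(k) exp(+2i*pi*n*k/N)."""
    X = np.asarray(X)
    if X.size == 0:
        raise ValueError("idft of an empty vector is undefined")
    return np.fft.ifft(X)


def dft_feature(
    x: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = DEFAULT_DFT_BAND,
    taper: bool = True,
) -> float:
    """In-band spectral centroid (mean frequency, Hz) of one window.

    A Hann taper reduces spectral leakage before the magnitude-squared
    spectrum is formed.  If the window carries no in-band power the band
    midpoint is returned with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("dft_feature needs a window of at least 2 samples")
    lo, hi = band
    if taper:
        x = x * np.hanning(x.size)
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    in_band = (freqs >= lo) & (freqs <= hi)
    power = spectrum[in_band]
    total = power.sum()
    if total <= np.finfo(float).tiny:
        midpoint = 0.5 * (lo + hi)
        logger.warning(
            "window has no power in the %g-%g Hz band; returning midpoint %g Hz",
            lo,
            hi,
            midpoint,
        )
        return midpoint
    return float(np.sum(freqs[in_band] * power) / total)


def wt_feature(x: np.ndarray, spec: WaveletSpec | None = None) -> float:
    """Log-energy of the detail coefficients at the configured level.

    Uses an orthogonal discrete wavelet decomposition in periodization mode,
    so coefficient energy equals the energy of the corresponding band-limited
    signal component.  Returns ``log(1 + sum c^2)``, which is zero for an
    all-zero window and strictly increasing in the signal's amplitude scale.
    """
    spec = spec or WaveletSpec()
    x = np.asarray(x, dtype=float)
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(spec.wavelet).dec_len)
    if spec.level > max_level:
        raise ValueError(
            f"window of {x.size} samples supports at most level {max_level} "
            f"for wavelet {spec.wavelet!r} (requested {spec.level})"
        )
    coeffs = pywt.wavedec(x, spec.wavelet, level=spec.level, mode="periodization")
    detail = coeffs[1]  # detail band at the deepest (configured) level
    return float(np.log1p(np.sum(detail**2)))


def extract_features(
    rec: EmgRecording,
    wspec: WindowingSpec | None = None,
    wavespec: WaveletSpec | None = None,
    dft_band: tuple[float, float] = DEFAULT_DFT_BAND,
) -> FeatureMatrix:
    """Window a preprocessed recording and compute per-channel features.

    Columns are channel-major: ``[ch1_mav, ch1_dft, ch1_wt, ch2_mav, ...]``,
    giving ``3 * n_channels`` features per window (15 for the default
    five-muscle map).
    """
    wspec = wspec or WindowingSpec()
    wavespec = wavespec or WaveletSpec()
    windows, centers = window_signal(rec, wspec)
    n_windows, _, n_channels = windows.shape
    values = np.empty((n_windows, 3 * n_channels))
    for w in range(n_windows):
        for c in range(n_channels):
            x = windows[w, :, c]
            values[w, 3 * c] = mav(x)
            values[w, 3 * c + 1] = dft_feature(x, rec.sample_rate, dft_band)
            values[w, 3 * c + 2] = wt_feature(x, wavespec)
    names = tuple(
        f"{ch}_{kind}" for ch in rec.channel_names for kind in FEATURE_KINDS
    )
    return FeatureMatrix(centers, values, names)
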