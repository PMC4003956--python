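"""The 26-parameter spectral feature vector of a tremor test.

From one scalar analysis channel (typically the deviation from the test
pattern) the extractor computes:

- parameters 1-9 from the Welch power spectral density: the maximum PSD
  value and its frequency, the 1st/2nd/4th/5th spectral moments, and the
  numbers of spectrum samples above 0.72%, 2.42% and 95.3% of the maximum;
- parameters 10-26 from higher-order spectra: sums, log-sums, frequency
  moments and threshold counts of the bispectrum diagonal |B(f, f)| and of
  the full bispectrum magnitude over its principal region, and of the
  trispectrum diagonal |T(f, f, f)|.

Spectral moments treat the (non-negative) spectrum as a normalized
distribution over frequency: m_k = sum f^k S(f) / sum S(f), taken about
zero.  Threshold counts are relative to that spectrum's own maximum.
Higher-order spectra are direct (FFT-based) estimates averaged over
Hann-windowed segments; B(f1, f2) = E[X(f1) X(f2) X*(f1+f2)] and
T(f, f, f) = E[X(f)^3 X*(3f)], with the diagonal grids restricted to
2f <= Nyquist and 3f <= Nyquist respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.signal import get_window

from .patterns import Pattern, deviation_series
from .simulate import Recording

__all__ = [
    "SpectralSettings",
    "SpectralEstimate",
    "FeatureVector",
    "FEATURE_NAMES",
    "estimate_psd",
    "psd_params",
    "bispectrum_diag",
    "trispectrum_diag",
    "bicoherence_diag",
    "hos_params",
    "extract_features",
    "spectrogram",
]

#: log-floor for rows 12, 13 and 16 so logarithms are total
LOG_EPS = 1e-12

FEATURE_NAMES = tuple(f"p{i}" for i in range(1, 27))

#: PSD threshold-count levels (fractions of the spectrum maximum), rows 6-8.
PSD_COUNT_LEVELS = (0.0072, 0.0242, 0.953)
#: Bispectrum-diagonal count levels, rows 22-23.
BISP_COUNT_LEVELS = (0.0029, 0.043)
#: Trispectrum-diagonal count levels, rows 24-25.
TRISP_COUNT_LEVELS = (0.0015, 5.6e-8)


@dataclass(frozen=True)
class SpectralSettings:
    """Estimator settings shared by the PSD and higher-order estimates."""

    window: str = "hann"
    nperseg: int = 256
    noverlap: Optional[int] = None   # default: 50% overlap
    detrend: Optional[str] = "linear"

    @property
    def hop(self) -> int:
        nov = self.nperseg // 2 if self.noverlap is None else self.noverlap
        return self.nperseg - nov

    @property
    def overlap(self) -> int:
        return self.nperseg // 2 if self.noverlap is None else self.noverlap


@dataclass
class SpectralEstimate:
    """PSD and higher-order spectral estimates of one scalar series."""

    settings: SpectralSettings
    fs: float
    freqs: Optional[np.ndarray] = None
    psd: Optional[np.ndarray] = None
    bisp_freqs: Optional[np.ndarray] = None
    bisp_diag: Optional[np.ndarray] = None
    bisp_mag: Optional[np.ndarray] = None    # |B(f1,f2)| principal region
    bisp_mask: Optional[np.ndarray] = None   # True where (f1,f2) is in-region
    trisp_freqs: Optional[np.ndarray] = None
    trisp_diag: Optional[np.ndarray] = None


def _segments(series: np.ndarray, st: SpectralSettings) -> np.ndarray:
    """Hann-windowed (and optionally detrended) segments, shape (n_seg, nperseg)."""
    x = np.asarray(series, float)
    n, hop = st.nperseg, st.hop
    if x.size < n:
        raise ValueError(
            f"series has {x.size} samples; at least nperseg={n} are required")
    n_seg = (x.size - n) // hop + 1
    w = get_window(st.window, n, fftbins=True)
    out = np.empty((n_seg, n))
    for i in range(n_seg):
        seg = x[i * hop: i * hop + n]
        if st.detrend is not None:
            seg = sps.detrend(seg, type=st.detrend)
        out[i] = w * seg
    return out


def estimate_psd(series, fs: float,
                 settings: SpectralSettings = SpectralSettings(),
                 est: Optional[SpectralEstimate] = None) -> SpectralEstimate:
    """One-sided Welch PSD (Hann window, 256-sample segments, 50% overlap,
    per-segment linear detrend by default)."""
    x = np.asarray(series, float)
    if x.size < settings.nperseg:
        raise ValueError(
            f"series has {x.size} samples; at least nperseg={settings.nperseg}"
            " are required for the PSD estimate")
    freqs, psd = sps.welch(
        x, fs=fs, window=settings.window, nperseg=settings.nperseg,
        noverlap=settings.overlap,
        detrend=False if settings.detrend is None else settings.detrend,
        return_onesided=True, scaling="density")
    if est is None:
        est = SpectralEstimate(settings=settings, fs=fs)
    est.freqs, est.psd = freqs, psd
    return est


def _spectral_moment(freqs: np.ndarray, weights: np.ndarray, k: int) -> float:
    total = float(np.sum(weights))
    if total == 0.0:
        return 0.0
    return float(np.sum(freqs**k * weights) / total)


def psd_params(est: SpectralEstimate) -> np.ndarray:
    """Parameters 1-9 from the PSD (see module docstring)."""
    if est.psd is None:
        raise ValueError("PSD has not been estimated")
    f, p = est.freqs, est.psd
    pmax = float(np.max(p))
    out = np.empty(9)
    out[0] = pmax
    out[1] = float(f[int(np.argmax(p))])
    out[2] = _spectral_moment(f, p, 1)
    out[3] = _spectral_moment(f, p, 2)
    out[4] = _spectral_moment(f, p, 4)
    for j, lvl in enumerate(PSD_COUNT_LEVELS):
        out[5 + j] = int(np.count_nonzero(p > lvl * pmax))
    out[8] = _spectral_moment(f, p, 5)
    return out


def bispectrum_diag(series, fs: float,
                    settings: SpectralSettings = SpectralSettings(),
                    est: Optional[SpectralEstimate] = None) -> SpectralEstimate:
    """Segment-averaged direct bispectrum estimate.

    Stores the diagonal |B(f, f)| on the grid with 2f <= Nyquist and the
    full magnitude |B(f1, f2)| over the principal region
    0 <= f2 <= f1, f1 + f2 <= Nyquist (needed for the sum and log-sum
    parameters).  Requires at least 2 * nperseg samples.
    """
    x = np.asarray(series, float)
    if x.size < 2 * settings.nperseg:
        raise ValueError(
            f"series has {x.size} samples; at least {2 * settings.nperseg} "
            "are required for the bispectrum estimate")
    segs = _segments(x, settings)
    n = settings.nperseg
    X = np.fft.fft(segs, axis=1)
    half = n // 2
    kd = np.arange(half // 2 + 1)          # 2f <= Nyquist
    diag_acc = np.mean(X[:, kd] ** 2 * np.conj(X[:, 2 * kd]), axis=0)

    k1 = np.arange(half + 1)
    K1, K2 = np.meshgrid(k1, k1, indexing="ij")
    mask = (K2 <= K1) & (K1 + K2 <= half)
    full = np.zeros((half + 1, half + 1), complex)
    i1, i2 = np.nonzero(mask)
    full[i1, i2] = np.mean(X[:, i1] * X[:, i2] * np.conj(X[:, i1 + i2]), axis=0)

    if est is None:
        est = SpectralEstimate(settings=settings, fs=fs)
    est.bisp_freqs = kd * fs / n
    est.bisp_diag = np.abs(diag_acc)
    est.bisp_mag = np.abs(full)
    est.bisp_mask = mask
    return est


def trispectrum_diag(series, fs: float,
                     settings: SpectralSettings = SpectralSettings(),
                     est: Optional[SpectralEstimate] = None) -> SpectralEstimate:
    """Segment-averaged trispectrum diagonal |T(f, f, f)|, 3f <= Nyquist."""
    x = np.asarray(series, float)
    if x.size < 2 * settings.nperseg:
        raise ValueError(
            f"series has {x.size} samples; at least {2 * settings.nperseg} "
            "are required for the trispectrum estimate")
    segs = _segments(x, settings)
    n = settings.nperseg
    X = np.fft.fft(segs, axis=1)
    half = n // 2
    kd = np.arange(half // 3 + 1)          # 3f <= Nyquist
    diag_acc = np.mean(X[:, kd] ** 3 * np.conj(X[:, 3 * kd]), axis=0)
    if est is None:
        est = SpectralEstimate(settings=settings, fs=fs)
    est.trisp_freqs = kd * fs / n
    est.trisp_diag = np.abs(diag_acc)
    return est


def bicoherence_diag(series, fs: float,
                     settings: SpectralSettings = SpectralSettings()) -> np.ndarray:
    """Squared bicoherence on the diagonal, b^2(f, f) in [0, 1].

    Normalizes the segment-averaged triple product by the segment-averaged
    power factors; used as a Gaussianity sanity check (near zero for linear
    Gaussian signals, large under quadratic phase coupling).
    """
    segs = _segments(np.asarray(series, float), settings)
    n = settings.nperseg
    X = np.fft.fft(segs, axis=1)
    half = n // 2
    kd = np.arange(half // 2 + 1)
    triple = np.mean(X[:, kd] ** 2 * np.conj(X[:, 2 * kd]), axis=0)
    denom = (np.mean(np.abs(X[:, kd] ** 2) ** 2, axis=0)
             * np.mean(np.abs(X[:, 2 * kd]) ** 2, axis=0))
    out = np.zeros(kd.size)
    nz = denom > 0
    out[nz] = np.abs(triple[nz]) ** 2 / denom[nz]
    return out


def _log_sum(values: np.ndarray) -> float:
    """Sum of log(v + eps), defined as 0 for an all-zero spectrum."""
    if not np.any(values > 0):
        return 0.0
    return float(np.sum(np.log(values + LOG_EPS)))


def hos_params(est: SpectralEstimate) -> np.ndarray:
    """Parameters 10-26 from the bispectrum and trispectrum estimates."""
    if est.bisp_diag is None or est.trisp_diag is None:
        raise ValueError("bispectrum and trispectrum have not been estimated")
    bd, bf = est.bisp_diag, est.bisp_freqs
    td, tf = est.trisp_diag, est.trisp_freqs
    b_all = est.bisp_mag[est.bisp_mask]
    out = np.empty(17)
    out[0] = float(np.sum(bd))                       # p10
    out[1] = float(np.sum(b_all))                    # p11
    out[2] = _log_sum(bd)                            # p12
    out[3] = _log_sum(b_all)                         # p13
    out[4] = _spectral_moment(bf, bd, 1)             # p14
    out[5] = _spectral_moment(bf, bd, 2)             # p15
    # p16: 1st moment with log(bd + eps) as the (signed) weight
    log_bd = np.log(bd + LOG_EPS) if np.any(bd > 0) else np.zeros_like(bd)
    out[6] = _spectral_moment(bf, log_bd, 1) if np.any(log_bd != 0) else 0.0
    out[7] = float(np.max(td))                       # p17
    out[8] = float(np.sum(td) / td.size)             # p18: normalized sum
    out[9] = _spectral_moment(tf, td, 1)             # p19
    out[10] = _spectral_moment(tf, td, 2)            # p20
    out[11] = _spectral_moment(tf, td, 3)            # p21
    bmax, tmax = float(np.max(bd)), float(np.max(td))
    out[12] = int(np.count_nonzero(bd > BISP_COUNT_LEVELS[0] * bmax))   # p22
    out[13] = int(np.count_nonzero(bd > BISP_COUNT_LEVELS[1] * bmax))   # p23
    out[14] = int(np.count_nonzero(td > TRISP_COUNT_LEVELS[0] * tmax))  # p24
    out[15] = int(np.count_nonzero(td > TRISP_COUNT_LEVELS[1] * tmax))  # p25
    out[16] = _spectral_moment(tf, td, 5)            # p26
    return out


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 26 parameters computed from one scalar channel."""

    values: np.ndarray
    channel_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (26,):
            raise ValueError("a feature vector has exactly 26 values")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))


def spectral_estimate(series, fs: float,
                      settings: SpectralSettings = SpectralSettings()) -> SpectralEstimate:
    """PSD + bispectrum + trispectrum estimates of one scalar series."""
    est = SpectralEstimate(settings=settings, fs=fs)
    estimate_psd(series, fs, settings, est)
    bispectrum_diag(series, fs, settings, est)
    trispectrum_diag(series, fs, settings, est)
    return est


def extract_features(recording: Recording, pattern: Pattern,
                     settings: SpectralSettings = SpectralSettings()) -> FeatureVector:
    """Compute the 26-parameter vector for one recording.

    The analysis channel is the deviation series for patterns with a path
    or target, and the highest-variance detrended axis for the rest
    pattern; the channel choice is recorded in ``channel_id``.
    """
    series = deviation_series(recording, pattern)
    channel = ("detrended_axis_max_var" if pattern.id == 1
               else "deviation_from_reference")
    est = spectral_estimate(series, recording.fs, settings)
    values = np.concatenate([psd_params(est), hos_params(est)])
    return FeatureVector(values=values, channel_id=channel)


def spectrogram(series, fs: float, window_len: int = 256):
    """Hann-windowed STFT magnitude (utility; not part of the 26 features).

    Returns ``(freqs, times, magnitude)`` with magnitude shaped
    (n_freqs, n_times).
    """
    x = np.asarray(series, float)
    if window_len > x.size:
        raise ValueError(
            f"window_len={window_len} exceeds series length {x.size}")
    w = get_window("hann", window_len, fftbins=True)
    sft = sps.ShortTimeFFT(w, hop=window_len // 2, fs=fs,
                           mfft=window_len, scale_to="magnitude")
    S = sft.stft(x)
    times = sft.t(x.size)
    return sft.f, times, np.abs(S)
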