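"""Literature feature set (FeatSet_A): 222 features per window.

For each of the six inertial channels, 37 descriptors:

* 20 time-domain: mean, variance, standard deviation, skewness, kurtosis,
  min, max, 25th/75th percentiles, interquartile range, and the first ten
  lags of the normalized autocorrelation sequence;
* 3 frequency-domain: mean frequency, median frequency and Shannon
  spectral entropy of the periodogram of the mean-removed signal;
* 14 time-frequency: Euclidean norms of the approximation and detail
  coefficients at each of seven levels of a discrete wavelet transform
  cascade (Daubechies-4, symmetric padding by default).

Conventions that the window statistics follow: population (biased)
moments; kurtosis is Pearson's (not excess-adjusted); skewness and
kurtosis of a constant signal are 0 by the 0/0 convention; the
autocorrelation uses the biased estimator normalized so that lag 0 would
equal 1 (lags 1-10 are returned).
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .dataset import Window

CHANNELS = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

TIME_NAMES = (
    "mean", "variance", "std", "skewness", "kurtosis", "min", "max",
    "p25", "p75", "iqr",
    *[f"autocorr_lag{k}" for k in range(1, 11)],
)
FREQ_NAMES = ("mean_freq", "median_freq", "spectral_entropy")
DWT_NAMES = (
    *[f"dwt_approx_norm_l{j}" for j in range(1, 8)],
    *[f"dwt_detail_norm_l{j}" for j in range(1, 8)],
)
DESCRIPTORS = TIME_NAMES + FREQ_NAMES + DWT_NAMES  # 20 + 3 + 14 = 37

#: canonical channel-major feature order, 6 × 37 = 222 names
FEATSET_A_NAMES: tuple[str, ...] = tuple(
    f"{ch}__{d}" for ch in CHANNELS for d in DESCRIPTORS
)

DEFAULT_WAVELET = "db4"
DEFAULT_DWT_MODE = "symmetric"
DWT_LEVELS = 7


def time_features(channel: np.ndarray) -> np.ndarray:
    """The 20 time-domain descriptors of one channel (length >= 11)."""
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1 or x.size < 11:
        raise ValueError("channel must be 1-D with at least 11 samples (lag-10 autocorrelation)")
    mean = x.mean()
    var = x.var()  # population variance
    std = np.sqrt(var)
    if var == 0:
        skew = 0.0
        kurt = 0.0
    else:
        skew = float(sp_stats.skew(x, bias=True))
        kurt = float(sp_stats.kurtosis(x, fisher=False, bias=True))
    p25, p75 = np.percentile(x, [25, 75])
    xc = x - mean
    denom = xc @ xc  # n·var; autocorrelation normalized so lag 0 = 1
    if denom == 0:
        ac = np.zeros(10)
    else:
        ac = np.array([xc[:-k] @ xc[k:] for k in range(1, 11)]) / denom
    return np.array(
        [mean, var, std, skew, kurt, x.min(), x.max(), p25, p75, p75 - p25, *ac]
    )


def freq_features(channel: np.ndarray, fs: float) -> np.ndarray:
    """Mean frequency, median frequency, Shannon spectral entropy.

    The power spectral density is the periodogram of the mean-removed
    signal.  Mean frequency is the power-weighted average frequency;
    median frequency is where cumulative power first reaches half the
    total; entropy is −Σ p·log₂ p over the PSD normalized to sum 1.
    """
    x = np.asarray(channel, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.ndim != 1 or x.size < 8:
        raise ValueError("channel must be 1-D with at least 8 samples")
    xc = x - x.mean()
    if not np.any(xc):
        warnings.warn("zero signal after mean removal; frequency features set to 0")
        return np.zeros(3)
    freqs, psd = sp_signal.periodogram(xc, fs=fs, detrend=False)
    total = psd.sum()
    p = psd / total
    mean_freq = float(freqs @ p)
    median_freq = float(freqs[np.searchsorted(np.cumsum(p), 0.5)])
    nz = p[p > 0]
    entropy = float(-(nz @ np.log2(nz)))
    return np.array([mean_freq, median_freq, entropy])


def dwt_features(
    channel: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_DWT_MODE,
) -> np.ndarray:
    """Norms of approximation and detail coefficients at DWT levels 1-7.

    A single-step cascade: at each level the previous approximation is
    decomposed once more, and the Euclidean norm of both output bands is
    recorded, giving A1..A7 then D1..D7 (14 non-negative values).
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1 or x.size < 2**DWT_LEVELS:
        raise ValueError(f"channel must be 1-D with at least {2**DWT_LEVELS} samples")
    approx_norms, detail_norms = [], []
    a = x
    for _ in range(DWT_LEVELS):
        a, d = pywt.dwt(a, wavelet, mode=mode)
        approx_norms.append(np.linalg.norm(a))
        detail_norms.append(np.linalg.norm(d))
    return np.array(approx_norms + detail_norms)


def extract_featset_a(
    window: Window,
    wavelet: str = DEFAULT_WAVELET,
    dwt_mode: str = DEFAULT_DWT_MODE,
) -> np.ndarray:
    """The 222-vector for one window: 6 channels × (20 + 3 + 14)."""
    parts = []
    for ch in window.channels:
        parts.append(time_features(ch))
        parts.append(freq_features(ch, window.fs))
        parts.append(dwt_features(ch, wavelet=wavelet, mode=dwt_mode))
    return np.concatenate(parts)
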