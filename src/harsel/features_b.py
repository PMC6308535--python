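"""Biomechanics-derived time-domain feature set (FeatSet_B): 221 features.

Positive and negative peaks are the extrema reached between two
consecutive zero crossings of the (window-mean-removed) signal.  Per
channel, 33 descriptors:

* zero-crossing count (1);
* positive / negative peak counts (2);
* mean, standard deviation, max, min and range of peak *duration* for
  positive, negative and pooled peaks (15);
* the same five statistics of *time-to-peak* for the three categories (15).

A further 23 descriptors come from integrated signals — velocity and
displacement proxies: single and double integration of vertical (y) and
antero-posterior (x) acceleration, and single integration of the
medio-lateral (z) rate of turn:

* mean of ∫acc_y and ∬acc_y (2);
* mean and RMS of ∫acc_x (2);
* RMS of ∬acc_x (1);
* positive / negative / total peak counts of ∫gyro_z (3);
* the five duration statistics for positive, negative and pooled peaks of
  ∫gyro_z (15).

Total: 6 × 33 + 23 = 221.

Conventions: the window mean is subtracted before zero-crossing/peak
analysis (raw vertical acceleration carries the ~9.81 m·s⁻² gravity
offset and would otherwise never cross zero) and before the first
integration; boundary segments before the first and after the last
crossing are excluded; empty peak categories yield 0 for all their
statistics; standard deviations are population form (single event → 0);
time-to-peak is measured from the segment's leading crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .dataset import Window

CHANNELS = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")
_STATS = ("mean", "std", "max", "min", "range")
_CATEGORIES = ("pos", "neg", "total")

PER_CHANNEL_NAMES: tuple[str, ...] = (
    "n_zero_crossings",
    "n_pos_peaks",
    "n_neg_peaks",
    *[f"duration_{c}_{s}" for c in _CATEGORIES for s in _STATS],
    *[f"time_to_peak_{c}_{s}" for c in _CATEGORIES for s in _STATS],
)  # 33

INTEGRATION_NAMES: tuple[str, ...] = (
    "int1_acc_y_mean",
    "int2_acc_y_mean",
    "int1_acc_x_mean",
    "int1_acc_x_rms",
    "int2_acc_x_rms",
    "int1_gyro_z_n_pos_peaks",
    "int1_gyro_z_n_neg_peaks",
    "int1_gyro_z_n_total_peaks",
    *[f"int1_gyro_z_duration_{c}_{s}" for c in _CATEGORIES for s in _STATS],
)  # 23

#: canonical order: 6 per-channel blocks of 33, then the 23 integration names
FEATSET_B_NAMES: tuple[str, ...] = tuple(
    f"B__{ch}__{d}" for ch in CHANNELS for d in PER_CHANNEL_NAMES
) + tuple(f"B__{d}" for d in INTEGRATION_NAMES)


@dataclass(frozen=True)
class PeakEvent:
    """One extremum between two consecutive zero crossings."""

    polarity: str  # "positive" | "negative"
    amplitude: float
    start_crossing: int
    end_crossing: int
    duration: float      # s
    time_to_peak: float  # s, from the segment's leading crossing

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        if not (self.start_crossing < self.end_crossing):
            raise ValueError("start_crossing must precede end_crossing")
        if not (0 <= self.time_to_peak <= self.duration):
            raise ValueError("time_to_peak must lie within the segment duration")


def zero_crossings(channel: np.ndarray, remove_mean: bool = True) -> np.ndarray:
    """Indices where the (mean-removed) signal strictly changes sign.

    The returned index is the first sample of the new sign.  Exact zeros
    inherit the previous sign (leading zeros inherit the first nonzero
    sign); an all-zero signal has no crossings.
    """
    x = np.asarray(channel, dtype=float)
    if x.size == 0:
        raise ValueError("channel must be non-empty")
    if remove_mean:
        x = x - x.mean()
    s = np.sign(x)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.array([], dtype=int)
    # propagate previous nonzero sign into exact zeros
    filled = s.copy()
    filled[: nz[0]] = s[nz[0]]
    for i in range(nz[0] + 1, len(filled)):
        if filled[i] == 0:
            filled[i] = filled[i - 1]
    return np.flatnonzero(filled[1:] != filled[:-1]) + 1


def peaks(
    channel: np.ndarray, fs: float, remove_mean: bool = True
) -> list[PeakEvent]:
    """Peak events between consecutive zero crossings.

    Each inter-crossing segment contributes one positive or one negative
    peak according to its sign; the incomplete boundary segments before
    the first and after the last crossing are excluded.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(channel, dtype=float)
    if remove_mean and x.size:
        x = x - x.mean()
    zc = zero_crossings(x, remove_mean=False)
    events: list[PeakEvent] = []
    for a, b in zip(zc[:-1], zc[1:]):
        seg = x[a:b]
        positive = seg.sum() >= 0
        idx = int(np.argmax(seg) if positive else np.argmin(seg))
        events.append(
            PeakEvent(
                polarity="positive" if positive else "negative",
                amplitude=float(seg[idx]),
                start_crossing=int(a),
                end_crossing=int(b),
                duration=float((b - a) / fs),
                time_to_peak=float(idx / fs),
            )
        )
    return events


def _five_stats(values: np.ndarray) -> np.ndarray:
    """mean, population std, max, min, range; all 0 for an empty category."""
    if values.size == 0:
        return np.zeros(5)
    return np.array(
        [values.mean(), values.std(), values.max(), values.min(),
         values.max() - values.min()]
    )


def peak_statistics(events: list[PeakEvent], zc_count: int) -> np.ndarray:
    """The 33-vector of one channel's zero-crossing/peak descriptors."""
    pos = [e for e in events if e.polarity == "positive"]
    neg = [e for e in events if e.polarity == "negative"]
    out = [float(zc_count), float(len(pos)), float(len(neg))]
    for attr in ("duration", "time_to_peak"):
        for group in (pos, neg, events):
            out.extend(_five_stats(np.array([getattr(e, attr) for e in group])))
    return np.array(out)


def integrate(
    channel: np.ndarray, fs: float, order: int = 1, remove_mean: bool = True
) -> np.ndarray:
    """Cumulative trapezoidal integration with zero initial condition.

    The window mean is subtracted before the first integration only
    (a crude bias/gravity removal); ``order=2`` integrates twice.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    x = np.asarray(channel, dtype=float)
    if remove_mean:
        x = x - x.mean()
    y = cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    if order == 2:
        y = cumulative_trapezoid(y, dx=1.0 / fs, initial=0.0)
    return y


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def extract_featset_b(window: Window, remove_mean: bool = True) -> np.ndarray:
    """The 221-vector for one window (axis convention: x antero-posterior,
    y vertical, z medio-lateral)."""
    parts = []
    for ch in window.channels:
        zc = zero_crossings(ch, remove_mean=remove_mean)
        ev = peaks(ch, window.fs, remove_mean=remove_mean)
        parts.append(peak_statistics(ev, len(zc)))

    acc_x, acc_y = window.channels[0], window.channels[1]
    gyro_z = window.channels[5]
    v_y = integrate(acc_y, window.fs, order=1, remove_mean=remove_mean)
    d_y = integrate(acc_y, window.fs, order=2, remove_mean=remove_mean)
    v_x = integrate(acc_x, window.fs, order=1, remove_mean=remove_mean)
    d_x = integrate(acc_x, window.fs, order=2, remove_mean=remove_mean)
    w_z = integrate(gyro_z, window.fs, order=1, remove_mean=remove_mean)

    wz_events = peaks(w_z, window.fs, remove_mean=remove_mean)
    wz_pos = [e for e in wz_events if e.polarity == "positive"]
    wz_neg = [e for e in wz_events if e.polarity == "negative"]

    integ = [
        v_y.mean(), d_y.mean(), v_x.mean(), _rms(v_x), _rms(d_x),
        float(len(wz_pos)), float(len(wz_neg)), float(len(wz_events)),
    ]
    for group in (wz_pos, wz_neg, wz_events):
        integ.extend(_five_stats(np.array([e.duration for e in group])))
    parts.append(np.array(integ))
    return np.concatenate(parts)
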