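"""Rule-based static-activity stage.

Two fixed thresholds separate static from dynamic windows before any
machine learning runs:

* if the variance of the gyroscope z (medio-lateral) channel is below 600
  (samples in deg·s⁻¹), the window is static, otherwise dynamic;
* a static window with mean vertical (y) acceleration below 8.5 m·s⁻² is
  resting (activity 1), otherwise upright standing (activity 2).

Both comparisons are strict.  The 600 threshold is applied to the
variance computed from deg·s⁻¹ samples even though its nominal unit
would then be (deg·s⁻¹)²; the number, not the unit label, defines the
rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .dataset import Window

#: label emitted for windows that fail the static rule
DYNAMIC = 0
RESTING = 1
STANDING = 2


@dataclass(frozen=True)
class RuleThresholds:
    gyro_z_variance_threshold: float = 600.0  # variance of deg·s⁻¹ samples
    acc_y_mean_threshold: float = 8.5         # m·s⁻²

    def __post_init__(self) -> None:
        if self.gyro_z_variance_threshold <= 0 or self.acc_y_mean_threshold <= 0:
            raise ValueError("thresholds must be positive")


DEFAULT_THRESHOLDS = RuleThresholds()


def classify_window(
    window: Window, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> int:
    """Classify one window as RESTING (1), STANDING (2) or DYNAMIC (0)."""
    gyro_z = window.channels[5]
    if gyro_z.var() < thresholds.gyro_z_variance_threshold:
        acc_y = window.channels[1]
        return RESTING if acc_y.mean() < thresholds.acc_y_mean_threshold else STANDING
    return DYNAMIC


def classify_windows(
    windows: Sequence[Window], thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    return np.array([classify_window(w, thresholds) for w in windows], dtype=int)


class StaticRuleClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper around the fixed-threshold rule stage.

    ``fit`` is a no-op (the thresholds are not learned); ``predict``
    takes a sequence of windows and returns 1 (resting), 2 (standing)
    or 0 (dynamic) per window.
    """

    def __init__(self, gyro_z_variance_threshold: float = 600.0,
                 acc_y_mean_threshold: float = 8.5):
        self.gyro_z_variance_threshold = gyro_z_variance_threshold
        self.acc_y_mean_threshold = acc_y_mean_threshold

    def fit(self, windows: Sequence[Window] = (), y=None):
        self.thresholds_ = RuleThresholds(
            self.gyro_z_variance_threshold, self.acc_y_mean_threshold
        )
        self.classes_ = np.array([DYNAMIC, RESTING, STANDING])
        return self

    def predict(self, windows: Sequence[Window]) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            self.fit()
        return classify_windows(windows, self.thresholds_)
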