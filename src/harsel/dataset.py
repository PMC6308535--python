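"""Window segmentation, stratified train/validation split and min-max scaling.

Recordings are cut into 5-s windows with 3-s overlap (step 2 s); every
window inherits the recording's activity label.  The training set is a
stratified 10% sample per (subject, activity) stratum; the validation set
is the full window pool.  Features are min-max scaled with parameters
learned on the training rows only:

    v_norm = (v - min_train) / (max_train - min_train)

Training values land in [0, 1]; validation values may fall outside (no
clipping).  Constant features map to 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .synth import MimuRecording

KEY_COLUMNS = ("subject", "activity", "repetition", "window")


@dataclass
class Window:
    """One fixed-length labeled segment of the six inertial channels."""

    subject_id: int
    activity: int
    repetition: int
    window_index: int
    start_sample: int
    fs: float
    channels: np.ndarray  # 6 × m: acc x/y/z, gyro x/y/z

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.shape[0] != 6:
            raise ValueError("Window.channels must be 6 × m")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def key(self) -> tuple[int, int, int, int]:
        return (self.subject_id, self.activity, self.repetition, self.window_index)


def segment(
    recording: MimuRecording,
    window_s: float = 5.0,
    overlap_s: float = 3.0,
) -> list[Window]:
    """Cut one recording into sliding windows; the incomplete tail is dropped.

    With ``window_s - overlap_s`` step, a recording of n samples yields
    ``floor((n - m) / step) + 1`` windows (m = window length in samples);
    windows never span recording boundaries.
    """
    if not (0 <= overlap_s < window_s):
        raise ValueError("need 0 <= overlap_s < window_s")
    m = int(round(window_s * recording.fs))
    step = int(round((window_s - overlap_s) * recording.fs))
    n = recording.n_samples
    if m > n:
        warnings.warn(
            f"window ({window_s}s) longer than recording "
            f"({recording.duration_s:.3g}s); no windows produced"
        )
        return []
    channels = recording.channels()
    count = (n - m) // step + 1
    return [
        Window(
            subject_id=recording.subject_id,
            activity=recording.activity,
            repetition=recording.repetition,
            window_index=i,
            start_sample=i * step,
            fs=recording.fs,
            channels=channels[:, i * step : i * step + m],
        )
        for i in range(count)
    ]


class FeatureTable:
    """Windows × named features with labels and window keys.

    Thin wrapper over a pandas DataFrame of feature values (``X``), an
    integer label vector (``y``, activity codes) and a key frame aligned
    row-by-row (columns ``subject, activity, repetition, window``).
    """

    def __init__(self, X: pd.DataFrame, y: np.ndarray, keys: pd.DataFrame):
        X = X.reset_index(drop=True)
        keys = keys.reset_index(drop=True)
        y = np.asarray(y, dtype=int)
        if X.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if not (len(X) == len(y) == len(keys)):
            raise ValueError("X, y and keys must have the same number of rows")
        if tuple(keys.columns) != KEY_COLUMNS:
            raise ValueError(f"keys columns must be {KEY_COLUMNS}")
        self.X = X
        self.y = y
        self.keys = keys

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, mask_or_index) -> "FeatureTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureTable(
            self.X.iloc[idx], self.y[idx], self.keys.iloc[idx]
        )

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.X[list(names)], self.y, self.keys)

    @staticmethod
    def concat(tables: Iterable["FeatureTable"]) -> "FeatureTable":
        tables = list(tables)
        return FeatureTable(
            pd.concat([t.X for t in tables], ignore_index=True),
            np.concatenate([t.y for t in tables]),
            pd.concat([t.keys for t in tables], ignore_index=True),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.concat(
            [self.keys, pd.Series(self.y, name="activity_code"), self.X], axis=1
        )
        df.to_csv(path, index=False, float_format="%.12g")

    @staticmethod
    def from_csv(path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        keys = df[list(KEY_COLUMNS)]
        y = df["activity_code"].to_numpy()
        X = df.drop(columns=list(KEY_COLUMNS) + ["activity_code"])
        return FeatureTable(X, y, keys)


def windows_to_keys(windows: Sequence[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.subject_id, w.activity, w.repetition, w.window_index) for w in windows],
        columns=list(KEY_COLUMNS),
    )


def split_train(
    table: FeatureTable, fraction: float = 0.10, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified training draw; the validation set is the full pool.

    Per (subject, activity) stratum, ``round(fraction × stratum_size)``
    rows (minimum 1) are sampled without replacement into the training
    table.  The validation table contains every row of the input,
    training rows included, mirroring a protocol that scores candidate
    models on the total window pool.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    groups = table.keys.groupby(["subject", "activity"], sort=True).indices
    train_idx: list[np.ndarray] = []
    for key in sorted(groups):
        idx = np.sort(groups[key])
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty
            warnings.warn(f"empty stratum {key}, skipped")
            continue
        k = max(1, int(round(fraction * len(idx))))
        train_idx.append(rng.choice(idx, size=k, replace=False))
    sel = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], int)
    return table.subset(sel), table


@dataclass
class ScalingParams:
    """Per-feature training minima/maxima for min-max scaling."""

    feature_names: list[str]
    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.maximum < self.minimum):
            raise ValueError("maximum must be >= minimum for every feature")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "minimum": self.minimum.tolist(),
                    "maximum": self.maximum.tolist(),
                }
            )
        )

    @staticmethod
    def from_json(path: str | Path) -> "ScalingParams":
        d = json.loads(Path(path).read_text())
        return ScalingParams(d["feature_names"], d["minimum"], d["maximum"])


def fit_scaler(training: FeatureTable) -> ScalingParams:
    """Learn per-feature min/max on the training rows (backed by sklearn)."""
    scaler = MinMaxScaler().fit(training.X.to_numpy())
    constant = scaler.data_max_ == scaler.data_min_
    if constant.any():
        names = [n for n, c in zip(training.feature_names, constant) if c]
        warnings.warn(f"constant features map to 0 under min-max scaling: {names[:5]}"
                      + ("..." if len(names) > 5 else ""))
    return ScalingParams(training.feature_names, scaler.data_min_, scaler.data_max_)


def apply_scaler(table: FeatureTable, params: ScalingParams) -> FeatureTable:
    """Apply min-max scaling; out-of-range values are not clipped."""
    if table.feature_names != params.feature_names:
        raise ValueError("feature names do not match the fitted scaling parameters")
    span = params.maximum - params.minimum
    span = np.where(span == 0, 1.0, span)  # constant features -> 0
    values = (table.X.to_numpy() - params.minimum) / span
    return FeatureTable(
        pd.DataFrame(values, columns=params.feature_names), table.y, table.keys
    )
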