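"""Window → FeatureTable extraction front-end.

sklearn-style transformers over sequences of :class:`~harsel.dataset.Window`
objects (stateless; ``fit`` is a no-op, like text vectorizers operating on
raw documents).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import FeatureTable, Window, windows_to_keys
from . import features_a, features_b


class FeatureSetAExtractor(BaseEstimator, TransformerMixin):
    """222 literature features (time / frequency / wavelet domains)."""

    def __init__(self, wavelet: str = features_a.DEFAULT_WAVELET,
                 dwt_mode: str = features_a.DEFAULT_DWT_MODE):
        self.wavelet = wavelet
        self.dwt_mode = dwt_mode

    feature_names_ = list(features_a.FEATSET_A_NAMES)

    def fit(self, windows: Sequence[Window], y=None):
        return self

    def transform(self, windows: Sequence[Window]) -> FeatureTable:
        rows = np.array([
            features_a.extract_featset_a(w, wavelet=self.wavelet,
                                         dwt_mode=self.dwt_mode)
            for w in windows
        ])
        return _to_table(rows, windows, self.feature_names_)


class FeatureSetBExtractor(BaseEstimator, TransformerMixin):
    """221 biomechanics-derived time-domain features."""

    def __init__(self, remove_mean: bool = True):
        self.remove_mean = remove_mean

    feature_names_ = list(features_b.FEATSET_B_NAMES)

    def fit(self, windows: Sequence[Window], y=None):
        return self

    def transform(self, windows: Sequence[Window]) -> FeatureTable:
        rows = np.array([
            features_b.extract_featset_b(w, remove_mean=self.remove_mean)
            for w in windows
        ])
        return _to_table(rows, windows, self.feature_names_)


def _to_table(rows: np.ndarray, windows: Sequence[Window],
              names: list[str]) -> FeatureTable:
    if rows.size == 0:
        rows = rows.reshape(0, len(names))
    return FeatureTable(
        pd.DataFrame(rows, columns=names),
        np.array([w.activity for w in windows], dtype=int),
        windows_to_keys(list(windows)),
    )


def extract_features(windows: Sequence[Window], feature_set: str = "A",
                     **kwargs) -> FeatureTable:
    """Functional wrapper: extract FeatSet_A or FeatSet_B for windows."""
    fs = feature_set.upper()
    if fs == "A":
        return FeatureSetAExtractor(**kwargs).transform(windows)
    if fs == "B":
        return FeatureSetBExtractor(**kwargs).transform(windows)
    raise ValueError("feature_set must be 'A' or 'B'")
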