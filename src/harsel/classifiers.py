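"""The four classifier back-ends and their bit-string parameter decoders.

A candidate solution's parameter substring is decoded per classifier:

* KNN — 5 bits index a 32-value grid centred on Kin = round(√N) (N =
  training-set size): {Kin−16, …, Kin+15}, clipped to ≥ 1.
* FNN — 3 bits add 1-8 hidden layers beyond a first hidden layer of one
  neuron per selected feature; each further layer has half the previous
  layer's neurons (rounded half-up, floor 1).  Sigmoid hidden units, one
  linear output neuron whose rounded value is the predicted class.
* SVM — 2 bits choose the kernel {linear, gaussian, poly2, poly3}; 4 bits
  choose the penalty C: 0.5 if the decimal value is 0, 1 if it is 1,
  (value−1)×10 otherwise (so C ∈ {0.5, 1, 10, 20, …, 140}).  Multiclass by
  one-vs-one: k classes → k(k−1)/2 binary machines combined by majority
  voting, ties broken by summed decision margins then smallest code.
* DT — CART with the Gini index, grown until pure; no parameter bits.

Back-ends are scikit-learn estimators (KNeighborsClassifier, MLPRegressor,
SVC, DecisionTreeClassifier); the decoding, the one-vs-one combination and
the rounding rule are defined here.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.exceptions import ConvergenceWarning

from .dataset import FeatureTable

CLASSIFIER_KINDS = ("knn", "fnn", "svm", "dt")

#: parameter-substring length per classifier
PARAM_BITS = {"knn": 5, "fnn": 3, "svm": 6, "dt": 0}

KNN_GRID_SIZE = 32
KNN_GRID_OFFSET = -16  # grid spans Kin-16 .. Kin+15

SVM_KERNELS = ("linear", "gaussian", "poly2", "poly3")  # 2-bit table 00..11

DEFAULT_SVM_GAUSSIAN_SCALE = 10.0  # kernel scale s: K = exp(-||u-v||²/s²)
DEFAULT_FNN_MAX_ITER = 200


def bits_to_int(bits: Sequence[int]) -> int:
    """MSB-first binary string → integer."""
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return value


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def knn_grid(n_train: int) -> np.ndarray:
    """The 32 candidate K values around Kin = round(√n_train), clipped ≥ 1."""
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    kin = _round_half_up(np.sqrt(n_train))
    grid = kin + KNN_GRID_OFFSET + np.arange(KNN_GRID_SIZE)
    return np.maximum(grid, 1)


def decode_knn(code: int | Sequence[int], n_train: int) -> int:
    """Decode the 5-bit KNN substring to a neighbour count K."""
    idx = code if isinstance(code, (int, np.integer)) else bits_to_int(code)
    if not 0 <= idx < KNN_GRID_SIZE:
        raise ValueError(f"KNN code must be in [0, {KNN_GRID_SIZE}), got {idx}")
    return int(knn_grid(n_train)[idx])


def decode_fnn(code: int | Sequence[int], n_selected_features: int) -> list[int]:
    """Decode the 3-bit FNN substring to hidden-layer sizes.

    The first hidden layer has one neuron per selected feature; the code
    value adds 1-8 further layers, each half the previous (round half-up,
    floor 1).
    """
    value = code if isinstance(code, (int, np.integer)) else bits_to_int(code)
    if not 0 <= value < 8:
        raise ValueError(f"FNN code must be in [0, 8), got {value}")
    if n_selected_features < 1:
        raise ValueError("n_selected_features must be >= 1")
    sizes = [int(n_selected_features)]
    for _ in range(value + 1):
        sizes.append(max(1, _round_half_up(sizes[-1] / 2)))
    return sizes


def decode_svm(code: Sequence[int]) -> tuple[str, float]:
    """Decode the 6-bit SVM substring to (kernel, C)."""
    bits = list(code)
    if len(bits) != 6:
        raise ValueError("SVM code must have 6 bits (2 kernel + 4 C)")
    kernel = SVM_KERNELS[bits_to_int(bits[:2])]
    cdec = bits_to_int(bits[2:])
    if cdec == 0:
        c = 0.5
    elif cdec == 1:
        c = 1.0
    else:
        c = (cdec - 1) * 10.0
    return kernel, c


def decode_params(
    kind: str, param_bits: Sequence[int], n_train: int, n_selected_features: int
) -> dict:
    """Decode a parameter substring for any classifier kind."""
    if kind == "knn":
        return {"K": decode_knn(param_bits, n_train)}
    if kind == "fnn":
        return {"hidden_layers": decode_fnn(param_bits, n_selected_features)}
    if kind == "svm":
        kernel, c = decode_svm(param_bits)
        return {"kernel": kernel, "C": c}
    if kind == "dt":
        return {}
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass
class TrainedModel:
    """A fitted back-end plus the metadata needed to apply it."""

    kind: str
    params: dict
    feature_names: list[str]
    classes: np.ndarray
    estimator: object = None                 # single sklearn estimator
    pair_estimators: dict = field(default_factory=dict)  # SVM one-vs-one machines

    @property
    def n_binary_machines(self) -> int:
        return len(self.pair_estimators)

    def save(self, path: str | Path) -> None:
        """JSON metadata (kind, decoded params, features) + pickled state."""
        path = Path(path)
        path.with_suffix(".json").write_text(json.dumps({
            "kind": self.kind,
            "params": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                       for k, v in self.params.items()},
            "feature_names": self.feature_names,
            "classes": self.classes.tolist(),
        }, indent=2))
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _svc_for_kernel(kernel: str, c: float, gaussian_scale: float, seed: int) -> SVC:
    common = dict(C=c, decision_function_shape="ovo", random_state=seed)
    if kernel == "linear":
        return SVC(kernel="linear", **common)
    if kernel == "gaussian":
        return SVC(kernel="rbf", gamma=1.0 / gaussian_scale**2, **common)
    if kernel in ("poly2", "poly3"):
        degree = 2 if kernel == "poly2" else 3
        return SVC(kernel="poly", degree=degree, gamma="scale", coef0=1.0, **common)
    raise ValueError(f"unknown kernel {kernel!r}")


def train(
    kind: str,
    params: dict,
    training: FeatureTable,
    seed: int = 0,
    svm_gaussian_scale: float = DEFAULT_SVM_GAUSSIAN_SCALE,
    fnn_max_iter: int = DEFAULT_FNN_MAX_ITER,
) -> TrainedModel:
    """Fit one back-end on a (scaled, feature-selected) training table."""
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    if len(training) == 0:
        raise ValueError("training table is empty")
    X = training.X.to_numpy()
    y = training.y
    classes = np.unique(y)
    model = TrainedModel(kind=kind, params=dict(params),
                         feature_names=training.feature_names, classes=classes)

    if kind == "knn":
        k = int(params["K"])
        if k > len(y):
            warnings.warn(f"K={k} exceeds training size {len(y)}; clipped")
            k = len(y)
        model.estimator = KNeighborsClassifier(
            n_neighbors=k, metric="euclidean").fit(X, y)
    elif kind == "dt":
        model.estimator = DecisionTreeClassifier(
            criterion="gini", random_state=seed).fit(X, y)
    elif kind == "fnn":
        sizes = tuple(int(s) for s in params["hidden_layers"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.estimator = MLPRegressor(
                hidden_layer_sizes=sizes, activation="logistic",
                solver="adam", max_iter=fnn_max_iter, random_state=seed,
            ).fit(X, y.astype(float))
    else:  # svm: explicit one-vs-one bank of binary machines
        for a, b in combinations(classes, 2):
            mask = (y == a) | (y == b)
            svc = _svc_for_kernel(params["kernel"], params["C"],
                                  svm_gaussian_scale, seed)
            model.pair_estimators[(int(a), int(b))] = svc.fit(X[mask], y[mask])
    return model


def predict(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Predict activity codes for every row of the table."""
    if table.feature_names != model.feature_names:
        raise ValueError("table columns do not match the model's selected features")
    X = table.X.to_numpy()
    if model.kind in ("knn", "dt"):
        return model.estimator.predict(X).astype(int)
    if model.kind == "fnn":
        raw = model.estimator.predict(X)
        rounded = np.floor(raw + 0.5)  # round half up
        clipped = np.clip(rounded, model.classes.min(), model.classes.max())
        # snap to the nearest class actually present in training
        idx = np.abs(clipped[:, None] - model.classes[None, :]).argmin(axis=1)
        return model.classes[idx].astype(int)
    # svm one-vs-one majority vote, ties by summed margins then smallest code
    classes = model.classes
    pos = {c: i for i, c in enumerate(classes)}
    votes = np.zeros((len(X), len(classes)))
    margins = np.zeros((len(X), len(classes)))
    for (a, b), svc in model.pair_estimators.items():
        df = svc.decision_function(X)  # >0 favours svc.classes_[1]
        hi = int(svc.classes_[1])
        lo = int(svc.classes_[0])
        win_hi = df > 0
        votes[win_hi, pos[hi]] += 1
        votes[~win_hi, pos[lo]] += 1
        margins[:, pos[hi]] += df
        margins[:, pos[lo]] -= df
    out = np.empty(len(X), dtype=int)
    for i in range(len(X)):
        best = np.flatnonzero(votes[i] == votes[i].max())
        if len(best) > 1:
            m = margins[i, best]
            best = best[m == m.max()]
        out[i] = classes[best[0]]
    return out
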