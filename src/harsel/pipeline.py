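"""End-to-end experiment orchestration.

simulate → segment → rule stage → feature extraction (dynamic windows) →
stratified split → min-max scaling → GA feature/parameter search →
validation prediction → merge static + dynamic labels → majority vote →
score.  A single :class:`RunConfig` drives every stage; when an output
directory is given each stage writes its artifact and a manifest records
versions, seeds and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from . import classifiers as clf
from .dataset import (FeatureTable, apply_scaler, fit_scaler, segment,
                      split_train, windows_to_keys)
from .evaluate import EvaluationReport, majority_vote_by_recording, score
from .extract import extract_features
from .ga import GaConfig, run_ga, selected_feature_names
from .rules import DYNAMIC, DEFAULT_THRESHOLDS, RuleThresholds, classify_windows
from .synth import generate_cohort

logger = logging.getLogger("harsel")


@dataclass
class RunConfig:
    """Everything one experiment needs; validated on construction."""

    n_subjects: int = 6
    reps: int = 2
    duration_s: float = 60.0
    fs: float = 80.0
    window_s: float = 5.0
    overlap_s: float = 3.0
    feature_set: str = "B"          # "A" or "B"
    classifier: str = "svm"         # knn | fnn | svm | dt
    train_fraction: float = 0.10
    vote_group: int = 5
    gyro_z_variance_threshold: float = DEFAULT_THRESHOLDS.gyro_z_variance_threshold
    acc_y_mean_threshold: float = DEFAULT_THRESHOLDS.acc_y_mean_threshold
    ga: GaConfig = field(default_factory=lambda: GaConfig(
        population_size=20, max_iterations=6, plateau_patience=6))
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.ga, dict):
            self.ga = GaConfig(**self.ga)
        if self.n_subjects < 1 or self.reps < 1:
            raise ValueError("n_subjects and reps must be >= 1")
        if self.feature_set.upper() not in ("A", "B"):
            raise ValueError("feature_set must be 'A' or 'B'")
        if self.classifier not in clf.CLASSIFIER_KINDS:
            raise ValueError(f"classifier must be one of {clf.CLASSIFIER_KINDS}")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.vote_group < 1:
            raise ValueError("vote_group must be >= 1")

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        return RunConfig(**d)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(config: RunConfig) -> EvaluationReport:
    """Execute the full pipeline; returns the final evaluation report."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True))

    logger.info("simulating cohort: %d subjects x 7 activities x %d reps",
                config.n_subjects, config.reps)
    recordings = generate_cohort(config.n_subjects, config.reps,
                                 config.duration_s, config.fs, config.seed)

    windows = []
    for rec in recordings:
        windows.extend(segment(rec, config.window_s, config.overlap_s))
    if not windows:
        raise RuntimeError("segmentation produced no windows")
    truth = np.array([w.activity for w in windows], dtype=int)
    keys = windows_to_keys(windows)
    logger.info("segmented %d windows", len(windows))

    thresholds = RuleThresholds(config.gyro_z_variance_threshold,
                                config.acc_y_mean_threshold)
    rule_labels = classify_windows(windows, thresholds)
    dyn_mask = rule_labels == DYNAMIC
    logger.info("rule stage: %d static, %d dynamic windows",
                int((~dyn_mask).sum()), int(dyn_mask.sum()))

    predicted = rule_labels.copy()  # static windows keep their rule label

    if dyn_mask.any():
        dyn_windows = [w for w, d in zip(windows, dyn_mask) if d]
        table = extract_features(dyn_windows, config.feature_set)
        train_raw, val_raw = split_train(table, config.train_fraction, config.seed)
        params = fit_scaler(train_raw)
        training = apply_scaler(train_raw, params)
        validation = apply_scaler(val_raw, params)
        if out:
            training.to_csv(out / "training_features.csv")
            params.to_json(out / "scaling_params.json")

        logger.info("running GA (%s, FeatSet_%s, population %d)",
                    config.classifier, config.feature_set.upper(),
                    config.ga.population_size)
        best, history = run_ga(config.classifier, training, validation, config.ga)
        names = selected_feature_names(best, training.feature_names)
        decoded = clf.decode_params(config.classifier, best.param_bits,
                                    len(training), len(names))
        model = clf.train(config.classifier, decoded,
                          training.select_features(names), seed=config.ga.seed,
                          svm_gaussian_scale=config.ga.svm_gaussian_scale,
                          fnn_max_iter=config.ga.fnn_max_iter)
        predicted[dyn_mask] = clf.predict(model, validation.select_features(names))
        if out:
            (out / "ga_report.json").write_text(json.dumps({
                "classifier": config.classifier,
                "feature_set": config.feature_set.upper(),
                "best_fitness": best.fitness,
                "fitness_history": history,
                "n_selected_features": len(names),
                "selected_features": names,
                "decoded_params": decoded,
            }, indent=2))
    else:
        logger.info("no dynamic windows; GA stage skipped")

    smoothed = majority_vote_by_recording(predicted, keys, config.vote_group)
    report = score(smoothed, truth, keys)
    if out:
        import pandas as pd

        pd.concat([keys, pd.DataFrame({
            "truth": truth, "rule": rule_labels,
            "predicted": predicted, "voted": smoothed,
        })], axis=1).to_csv(out / "predictions.csv", index=False)
        report.to_json(out / "report.json")
        report.confusion.to_csv(out / "confusion_matrix.csv")
        (out / "manifest.json").write_text(json.dumps({
            "package_version": _pkg_version,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
        }, indent=2, sort_keys=True))
    logger.info("overall macro accuracy: %.4f", report.overall_accuracy)
    return report
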