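"""Majority-vote post-processing and performance metrics.

Window-level predictions within one recording are smoothed in consecutive
non-overlapping groups of five: the modal label is assigned to the whole
group (a final partial group votes over its own members; ties go to the
smallest activity code).  Performance is reported as per-activity
accuracy, overall (macro) accuracy, a confusion matrix, macro-averaged
precision and recall combined into

    F1 = 2 · precision · recall / (precision + recall),

and, when window keys are available, a per-subject accuracy table for the
paired two-tailed Student t-test used to compare feature sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.metrics import confusion_matrix as sk_confusion_matrix


def majority_vote(labels, group: int = 5) -> np.ndarray:
    """Blockwise modal smoothing of an ordered label sequence.

    Consecutive non-overlapping groups of ``group`` labels are each
    replaced by their mode (ties → smallest label); the trailing partial
    group votes over its own members.  ``group=1`` is the identity.
    """
    if group < 1:
        raise ValueError("group must be >= 1")
    labels = np.asarray(labels, dtype=int)
    out = labels.copy()
    for start in range(0, len(labels), group):
        block = labels[start : start + group]
        values, counts = np.unique(block, return_counts=True)
        out[start : start + group] = values[np.argmax(counts)]
    return out


def majority_vote_by_recording(
    labels, keys: pd.DataFrame, group: int = 5
) -> np.ndarray:
    """Apply :func:`majority_vote` separately within each recording
    (grouped by subject, activity, repetition; rows must be in window
    order within each recording)."""
    labels = np.asarray(labels, dtype=int)
    out = labels.copy()
    for _, idx in keys.groupby(
        ["subject", "activity", "repetition"], sort=False
    ).indices.items():
        idx = np.asarray(idx)
        out[idx] = majority_vote(labels[idx], group=group)
    return out


@dataclass
class EvaluationReport:
    per_activity_accuracy: dict[int, float]
    overall_accuracy: float  # unweighted mean across activities
    confusion: pd.DataFrame  # rows = truth, columns = predicted
    precision: float         # macro
    recall: float            # macro
    f1: float                # from macro precision/recall
    f1_micro: float
    per_subject_accuracy: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "per_activity_accuracy": {str(k): v for k, v in
                                      self.per_activity_accuracy.items()},
            "overall_accuracy": self.overall_accuracy,
            "confusion": self.confusion.to_dict(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "f1_micro": self.f1_micro,
        }
        if self.per_subject_accuracy is not None:
            d["per_subject_accuracy"] = self.per_subject_accuracy.to_dict(
                orient="records")
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def __str__(self) -> str:  # human-readable table
        lines = ["activity  accuracy"]
        for a, v in sorted(self.per_activity_accuracy.items()):
            lines.append(f"  A{a}      {v:8.4f}")
        lines.append(f"overall (macro) {self.overall_accuracy:.4f}")
        lines.append(f"precision {self.precision:.4f}  recall {self.recall:.4f}  "
                     f"F1 {self.f1:.4f}")
        return "\n".join(lines)


def score(predicted, truth, keys: pd.DataFrame | None = None) -> EvaluationReport:
    """Score predictions against truth.

    Per-activity accuracy is the within-class fraction correct; the
    overall accuracy is their unweighted (macro) mean, so duplicating the
    windows of one class leaves it unchanged.  Precision and recall are
    one-vs-rest per class, macro-averaged.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    labels = np.unique(np.concatenate([truth, predicted]))
    truth_labels = np.unique(truth)

    per_activity = {
        int(a): float(np.mean(predicted[truth == a] == a)) for a in truth_labels
    }
    overall = float(np.mean(list(per_activity.values())))

    cm = sk_confusion_matrix(truth, predicted, labels=labels)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)

    precisions, recalls = [], []
    for a in truth_labels:
        tp = np.sum((predicted == a) & (truth == a))
        fp = np.sum((predicted == a) & (truth != a))
        fn = np.sum((predicted != a) & (truth == a))
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
    precision = float(np.mean(precisions))
    recall = float(np.mean(recalls))
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    micro = float(np.mean(predicted == truth))  # micro P = R = F1 = accuracy
    per_subject = None
    if keys is not None:
        df = pd.DataFrame({
            "subject": keys["subject"].to_numpy(),
            "activity": truth,
            "correct": (predicted == truth).astype(float),
        })
        per_subject = (
            df.groupby(["subject", "activity"])["correct"].mean()
            .rename("accuracy").reset_index()
        )
    return EvaluationReport(
        per_activity_accuracy=per_activity,
        overall_accuracy=overall,
        confusion=confusion,
        precision=precision,
        recall=recall,
        f1=float(f1),
        f1_micro=micro,
        per_subject_accuracy=per_subject,
    )


def paired_ttest(acc_a, acc_b) -> tuple[float, float]:
    """Paired two-tailed Student t-test on per-subject accuracies.

    Degenerate conventions: identical vectors → (0.0, 1.0); zero-variance
    differences with nonzero mean → (±inf, 0.0), the direction of the
    mean difference.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D vectors with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2 * sp_stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


def plot_accuracy_bars(report: EvaluationReport, path: str | Path) -> None:
    """Per-activity accuracy bar chart (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    acts = sorted(report.per_activity_accuracy)
    vals = [report.per_activity_accuracy[a] for a in acts]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar([f"A{a}" for a in acts], vals)
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
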