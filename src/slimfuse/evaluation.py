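"""Residue-level binary-classification metrics.

ROC/AUC and PR/AP follow the standard descending-score threshold sweep (ties
grouped at a single threshold, trapezoidal AUC, step-wise AP with no
interpolation). FPR@TPR and precision@TPR report, for each TPR target, the
operating point at the *largest* threshold whose TPR reaches the target —
no interpolation between ROC points, so the numbers are exactly achievable
by a real cutoff. Evaluation is always run on the unbalanced validation or
test distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    auc as _trapezoid_auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)


@dataclass
class ScoreSet:
    """Paired prediction scores and binary ground-truth labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D vectors")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes are required for curve metrics")


@dataclass
class EvalReport:
    auc: float
    ap: float
    roc_points: list[tuple[float, float, float]]  # (fpr, tpr, threshold)
    pr_points: list[tuple[float, float, float]]  # (recall, precision, threshold)
    fpr_at_tpr: dict[float, float] = field(default_factory=dict)
    precision_at_tpr: dict[float, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "auc": self.auc,
            "ap": self.ap,
            "fpr_at_tpr": {str(k): v for k, v in self.fpr_at_tpr.items()},
            "precision_at_tpr": {str(k): v for k, v in self.precision_at_tpr.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def write_curves(self, roc_path: str | Path, pr_path: str | Path) -> None:
        with open(roc_path, "w") as fh:
            fh.write("fpr\ttpr\tthreshold\n")
            for fpr, tpr, t in self.roc_points:
                fh.write(f"{fpr:.6g}\t{tpr:.6g}\t{t:.6g}\n")
        with open(pr_path, "w") as fh:
            fh.write("recall\tprecision\tthreshold\n")
            for rec, prec, t in self.pr_points:
                fh.write(f"{rec:.6g}\t{prec:.6g}\t{t:.6g}\n")

    def format_table(self) -> str:
        """Aligned text table of the headline metrics and TPR operating points."""
        lines = [f"AUC: {self.auc:.4f}", f"AP:  {self.ap:.4f}", ""]
        targets = sorted(self.fpr_at_tpr)
        header = "metric     " + "".join(f"TPR={t:<8g}" for t in targets)
        lines.append(header)
        lines.append(
            "FPR        "
            + "".join(f"{self.fpr_at_tpr[t]:<12.4f}" for t in targets)
        )
        lines.append(
            "precision  "
            + "".join(f"{self.precision_at_tpr[t]:<12.4f}" for t in targets)
        )
        return "\n".join(lines)


def confusion_at_threshold(s: ScoreSet, t: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) when predicting positive iff score >= t."""
    pred = s.scores >= t
    tp = int(np.sum(pred & (s.labels == 1)))
    fp = int(np.sum(pred & (s.labels == 0)))
    tn = int(np.sum(~pred & (s.labels == 0)))
    fn = int(np.sum(~pred & (s.labels == 1)))
    return tp, fp, tn, fn


def roc_auc(s: ScoreSet) -> tuple[list[tuple[float, float, float]], float]:
    """ROC sweep over distinct scores (descending) and trapezoidal AUC."""
    s.require_both_classes()
    fpr, tpr, thresholds = roc_curve(s.labels, s.scores, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist(), thresholds.tolist()))
    return points, float(_trapezoid_auc(fpr, tpr))


def pr_ap(s: ScoreSet) -> tuple[list[tuple[float, float, float]], float]:
    """Precision-recall sweep and step-wise average precision."""
    if not np.any(s.labels == 1):
        raise ValueError("average precision needs at least one positive")
    precision, recall, thresholds = precision_recall_curve(s.labels, s.scores)
    # drop the final (recall 0, precision 1) sentinel that has no threshold
    points = [
        (float(recall[i]), float(precision[i]), float(thresholds[i]))
        for i in range(len(thresholds))
    ]
    ap = float(average_precision_score(s.labels, s.scores))
    return points, ap


def _threshold_for_tpr(s: ScoreSet, target: float) -> float:
    """Largest threshold whose TPR reaches ``target``.

    Achievable TPRs are multiples of 1/#positives; no interpolation is done.
    """
    if not 0 < target <= 1:
        raise ValueError(f"TPR target {target} outside (0, 1]")
    pos_scores = np.sort(s.scores[s.labels == 1])[::-1]
    if len(pos_scores) == 0:
        raise ValueError("no positive labels")
    n_needed = int(np.ceil(target * len(pos_scores)))
    # threshold at the n-th highest positive score captures >= n positives
    return float(pos_scores[n_needed - 1])


def fpr_at_tpr(s: ScoreSet, targets: Sequence[float] = (0.2, 0.3, 0.4)) -> dict[float, float]:
    """FPR at the operating point where TPR first reaches each target."""
    s.require_both_classes()
    out: dict[float, float] = {}
    for target in targets:
        t = _threshold_for_tpr(s, target)
        _, fp, tn, _ = confusion_at_threshold(s, t)
        out[float(target)] = fp / (fp + tn)
    return out


def precision_at_tpr(
    s: ScoreSet, targets: Sequence[float] = (0.2, 0.3, 0.4)
) -> dict[float, float]:
    """Precision at the same operating points as :func:`fpr_at_tpr`."""
    s.require_both_classes()
    out: dict[float, float] = {}
    for target in targets:
        t = _threshold_for_tpr(s, target)
        tp, fp, _, _ = confusion_at_threshold(s, t)
        out[float(target)] = tp / (tp + fp)
    return out


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    targets: Sequence[float] = (0.2, 0.3, 0.4),
) -> EvalReport:
    """Full residue-level report: ROC/AUC, PR/AP and the TPR operating points."""
    s = ScoreSet(scores, labels)
    roc_points, auc_val = roc_auc(s)
    pr_points, ap_val = pr_ap(s)
    return EvalReport(
        auc=auc_val,
        ap=ap_val,
        roc_points=roc_points,
        pr_points=pr_points,
        fpr_at_tpr=fpr_at_tpr(s, targets),
        precision_at_tpr=precision_at_tpr(s, targets),
    )
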