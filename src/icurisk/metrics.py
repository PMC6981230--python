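"""Evaluation protocol: ranking metrics with patient-level bootstrap CIs.

Point metrics (average precision, AUROC) are computed with scikit-learn;
threshold-based quantities (best F1 over all thresholds, the Youden-optimal
operating point) scan the full ROC / precision-recall curves. Confidence
intervals resample *patients* (with all their stays, with multiplicity)
rather than individual stays, so within-patient clustering is respected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, \
    roc_auc_score, roc_curve

__all__ = [
    "average_precision", "auroc", "best_f1", "youden_operating_point",
    "bootstrap_ci", "evaluate", "EvalReport",
]


def _check(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    return labels, scores


def average_precision(labels, scores) -> float:
    """Area under the precision-recall curve as the step-wise sum
    ``sum_n (R_n - R_{n-1}) P_n`` over descending-score thresholds."""
    labels, scores = _check(labels, scores)
    if labels.sum() == 0:
        raise ValueError("average precision is undefined without positives")
    return float(average_precision_score(labels, scores))


def auroc(labels, scores) -> float:
    """AUROC (Mann-Whitney rank statistic with tie correction)."""
    labels, scores = _check(labels, scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def best_f1(labels, scores) -> float:
    """F1 maximised over all thresholds between distinct scores."""
    labels, scores = _check(labels, scores)
    if labels.sum() == 0:
        raise ValueError("F1 is undefined without positives")
    precision, recall, _ = precision_recall_curve(labels, scores)
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    return float(f1.max())


def youden_operating_point(labels, scores) -> tuple[float, float]:
    """(sensitivity, specificity) at the threshold maximising Youden's J.

    Ties in J are broken toward higher sensitivity; with completely
    uninformative scores this returns (1.0, 0.0) — classify everyone
    positive.
    """
    labels, scores = _check(labels, scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("the operating point needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    # roc_curve orders thresholds descending, so tpr is non-decreasing:
    # the last tied index has the highest sensitivity
    k = best[np.argmax(tpr[best])]
    return float(tpr[k]), float(1.0 - fpr[k])


def bootstrap_ci(metric, labels, scores, patient_ids, n_boot: int = 100,
                 seed: int = 0) -> tuple[float, float, float]:
    """Mean and 95% percentile CI of ``metric`` over patient-level resamples.

    Each replicate draws patients with replacement and takes all their stays
    (with multiplicity), so a patient's stays are never split across
    replicates. Replicates where the metric is undefined (single-class
    resample) are redrawn deterministically by walking the seed sequence.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    patient_ids = np.asarray(patient_ids)
    values = _bootstrap_values([metric], labels, scores, patient_ids, n_boot, seed)[0]
    return float(np.mean(values)), float(np.percentile(values, 2.5)), \
        float(np.percentile(values, 97.5))


def _bootstrap_values(metrics: list, labels, scores, patient_ids,
                      n_boot: int, seed: int) -> list[np.ndarray]:
    unique = np.unique(patient_ids)
    by_patient = {p: np.flatnonzero(patient_ids == p) for p in unique}
    rng = np.random.default_rng(seed)
    out: list[list[float]] = [[] for _ in metrics]
    replicates = 0
    attempts = 0
    while replicates < n_boot and attempts < 20 * n_boot:
        attempts += 1
        chosen = rng.choice(unique, size=len(unique), replace=True)
        idx = np.concatenate([by_patient[p] for p in chosen])
        if len(np.unique(labels[idx])) < 2:
            continue  # metric undefined on a single-class resample
        for vals, metric in zip(out, metrics):
            vals.append(metric(labels[idx], scores[idx]))
        replicates += 1
    if replicates < n_boot:
        raise ValueError("could not draw bootstrap replicates with both classes")
    return [np.asarray(v) for v in out]


@dataclass
class EvalReport:
    """Point estimates with 95% bootstrap CIs for the five reported metrics."""
    average_precision: tuple[float, float, float]
    auroc: tuple[float, float, float]
    f1: tuple[float, float, float]
    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]
    n_stays: int = 0
    n_patients: int = 0

    FIELDS = ("average_precision", "auroc", "f1", "sensitivity", "specificity")

    def to_dict(self) -> dict:
        d = {}
        for name in self.FIELDS:
            mean, lo, hi = getattr(self, name)
            d[name] = {"mean": mean, "ci_lower": lo, "ci_upper": hi}
        d["n_stays"] = self.n_stays
        d["n_patients"] = self.n_patients
        return d

    def to_markdown(self, label: str = "model") -> str:
        """One markdown table row (with header) in the report layout:
        mean [95% CI] per metric."""
        header = ("| Model | Average Precision | AUROC | F1-Score | "
                  "Sensitivity | Specificity |\n|---|---|---|---|---|---|")
        cells = []
        for name in self.FIELDS:
            mean, lo, hi = getattr(self, name)
            cells.append(f"{mean:.3f} [{lo:.3f},{hi:.3f}]")
        return header + f"\n| {label} | " + " | ".join(cells) + " |"

    def summary(self, label: str = "model") -> str:
        header = f"{'':28s}" + "".join(f"{n:>22s}" for n in
                                       ("AvgPrec", "AUROC", "F1", "Sens", "Spec"))
        cells = []
        for name in self.FIELDS:
            mean, lo, hi = getattr(self, name)
            cells.append(f"{mean:.3f} [{lo:.3f},{hi:.3f}]")
        return header + "\n" + f"{label:28s}" + "".join(f"{c:>22s}" for c in cells)


def evaluate(labels, scores, patient_ids, n_boot: int = 100, seed: int = 0) -> EvalReport:
    """All five metrics with shared patient-level bootstrap replicates."""
    labels, scores = _check(labels, scores)
    metric_fns = [
        average_precision, auroc, best_f1,
        lambda l, s: youden_operating_point(l, s)[0],
        lambda l, s: youden_operating_point(l, s)[1],
    ]
    values = _bootstrap_values(metric_fns, labels, scores,
                               np.asarray(patient_ids), n_boot, seed)
    summaries = []
    for vals in values:
        summaries.append((float(np.mean(vals)), float(np.percentile(vals, 2.5)),
                          float(np.percentile(vals, 97.5))))
    return EvalReport(*summaries, n_stays=len(labels),
                      n_patients=len(np.unique(patient_ids)))
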