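"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and scikit-learn):
metrics are computed by explicit enumeration over thresholds or pairs, so
they serve as independent oracles for the fast implementations.
"""

from __future__ import annotations

import numpy as np


def thresholds_between(scores: np.ndarray) -> list[float]:
    s = np.unique(scores)
    mids = [(a + b) / 2 for a, b in zip(s[:-1], s[1:])]
    return [-np.inf] + mids + [np.inf]


def confusion(labels, scores, thr) -> tuple[int, int, int, int]:
    pred = scores > thr
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def brute_average_precision(labels, scores) -> float:
    """Sum over descending-score thresholds of (R_n - R_{n-1}) * P_n,
    with tied scores grouped at one threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(np.unique(scores), reverse=True):
        pred = scores >= thr
        tp = np.sum(pred & (labels == 1))
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


def brute_auroc(labels, scores) -> float:
    """Pair-counting AUROC: ties between a positive and a negative score half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_best_f1(labels, scores) -> float:
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    best = 0.0
    for thr in thresholds_between(scores):
        tp, fp, fn, _ = confusion(labels, scores, thr)
        if tp == 0:
            continue
        f1 = 2 * tp / (2 * tp + fp + fn)
        best = max(best, f1)
    return best


def brute_youden(labels, scores) -> tuple[float, float]:
    """Exhaustive threshold scan; ties in J broken toward higher sensitivity."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    best_j, best = -np.inf, (0.0, 0.0)
    for thr in thresholds_between(scores):
        tp, fp, fn, tn = confusion(labels, scores, thr)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and sens > best[0]):
            best_j, best = j, (sens, spec)
    return best


def brute_dedupe(events, vital_codes):
    """Run-length scan keeping the latest element of each vital-code run."""
    out = []
    i = 0
    while i < len(events):
        code, t = events[i]
        if code in vital_codes:
            j = i
            while j + 1 < len(events) and events[j + 1][0] == code:
                j += 1
            out.append(events[j])
            i = j + 1
        else:
            out.append(events[i])
            i += 1
    return out
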