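"""Independent brute-force oracles used only by the tests.

These enumerate voxels (or score pairs) one by one and apply the metric
definitions directly, sharing no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np


def oracle_counts(pred: np.ndarray, truth: np.ndarray):
    """Voxel-by-voxel TP/FP/FN/TN tally."""
    tp = fp = fn = tn = 0
    for z in range(truth.shape[0]):
        for y in range(truth.shape[1]):
            for x in range(truth.shape[2]):
                p = int(pred[z, y, x]) != 0
                t = int(truth[z, y, x]) != 0
                if p and t:
                    tp += 1
                elif p and not t:
                    fp += 1
                elif not p and t:
                    fn += 1
                else:
                    tn += 1
    return tp, fp, fn, tn


def _div(num, den, empty=1.0):
    return num / den if den > 0 else empty


def oracle_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """All confusion-based metrics straight from the definitions."""
    tp, fp, fn, tn = oracle_counts(pred, truth)
    total = tp + fp + fn + tn
    ji_f = _div(tp, tp + fp + fn)
    ji_b = _div(tn, tn + fp + fn)
    return {
        "JI_F": ji_f,
        "JI_B": ji_b,
        "m_IoU": (ji_f + ji_b) / 2,
        "DSC": _div(2 * tp, 2 * tp + fp + fn),
        "accuracy": (tp + tn) / total,
        "error_rate": (fp + fn) / total,
        "precision": _div(tp, tp + fp),
        "recall": _div(tp, tp + fn),
        "TPR": _div(tp, tp + fn),
        "TNR": _div(tn, tn + fp),
    }


def oracle_auroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """All-pairs Mann-Whitney statistic: ties count one half."""
    s = np.asarray(scores, dtype=float).ravel()
    t = np.asarray(truth).ravel().astype(bool)
    pos = s[t]
    neg = s[~t]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUROC undefined for single-class truth")
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (pos.size * neg.size)
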