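"""Agreement and classification metrics.

Cohen's kappa is the primary performance measure: unlike accuracy it
corrects for the agreement expected by chance given both label marginals,
which matters for the imbalanced multi-class problems typical of activity
recognition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score


@dataclass(frozen=True)
class KappaStat:
    """Observed agreement p_o, chance agreement p_e and the kappa score
    kappa = (p_o - p_e) / (1 - p_e)."""

    p_o: float
    p_e: float
    kappa: float


def cohen_kappa(y_true, y_pred) -> KappaStat:
    """Cohen's kappa for two label sequences.

    p_o is the fraction of exact agreements; p_e = sum_c p_true(c) *
    p_pred(c).  The degenerate case p_e = 1 (both sequences constant and
    equal in marginals) is defined as kappa = 0 so pathological single-class
    folds do not abort batch runs.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(
            f"label sequences must be equal-length 1-d, got "
            f"{y_true.shape} vs {y_pred.shape}")
    n = len(y_true)
    if n == 0:
        raise ValueError("empty label sequences")
    p_o = float(np.mean(y_true == y_pred))
    classes = np.unique(np.concatenate([y_true, y_pred]))
    p_e = float(sum(np.mean(y_true == c) * np.mean(y_pred == c)
                    for c in classes))
    kappa = 0.0 if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    return KappaStat(p_o=p_o, p_e=p_e, kappa=float(kappa))


def classification_metrics(y_true, y_pred) -> dict[str, float]:
    """Accuracy, error rate and support-weighted F-score.

    The weighted F-score is the mean of per-class F1 weighted by true
    support; classes with no true and no predicted positives score 0.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label sequences must be equal-length 1-d")
    accuracy = float(np.mean(y_true == y_pred))
    y_true_s = y_true.astype(str)
    y_pred_s = y_pred.astype(str)
    labels = np.unique(y_true_s)
    weighted_f = float(f1_score(
        y_true_s, y_pred_s, labels=labels, average="weighted",
        zero_division=0))
    return {
        "accuracy": accuracy,
        "error_rate": 1.0 - accuracy,
        "weighted_f": weighted_f,
    }
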