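"""Cautious classification and accuracy/coverage evaluation.

A calibrated link predictor can *decline* to predict when its confidence
max(p, 1-p) falls below a cutoff, trading coverage (fraction of pairs
predicted) for accuracy among the retained predictions.  A cutoff of 0.5
retains everything; raising the cutoff can only shrink the retained set.

Note on terminology: the cutoff is a threshold on posterior confidence
(sometimes loosely called a "p-value cutoff" in the applied literature);
it is not a significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DataError

#: Default cutoff grid for accuracy/coverage curves.
DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.50, 1.00, 0.01), 2)) + (0.995, 0.999)


@dataclass
class PredictionSet:
    """Aligned prediction outputs for a set of pairs."""

    pair_ids: list[tuple[str, str]]
    phi: np.ndarray
    prob: np.ndarray
    predicted: np.ndarray
    retained: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pair_ids)
        for name in ("phi", "prob", "predicted", "retained"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise DataError(f"{name} length does not match pair ids")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_a": [a for a, _ in self.pair_ids],
            "node_b": [b for _, b in self.pair_ids],
            "phi": self.phi,
            "prob_link": self.prob,
            "predicted": self.predicted,
            "retained": self.retained.astype(int),
        })


def cautious_predict(probs, cutoff: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Retain only predictions with confidence max(p, 1-p) >= cutoff.

    Returns ``(retained_mask, predictions, coverage)``; predictions are +1
    where p >= 0.5 and -1 otherwise (computed for every point, retained or
    not).  ``cutoff`` must lie in [0.5, 1].
    """
    if not 0.5 <= cutoff <= 1.0:
        raise DataError(f"cutoff must be in [0.5, 1], got {cutoff}")
    probs = np.asarray(probs, dtype=float)
    confidence = np.maximum(probs, 1.0 - probs)
    retained = confidence >= cutoff
    predictions = np.where(probs >= 0.5, 1, -1)
    coverage = float(retained.mean()) if len(retained) else 0.0
    return retained, predictions, coverage


def accuracy_coverage_curve(probs, labels, cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Accuracy among retained points and coverage, per confidence cutoff.

    Accuracy is NaN at cutoffs where nothing is retained.  Returns a frame
    with columns (cutoff, n_retained, coverage, accuracy), one row per
    cutoff in grid order.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise DataError("probs and labels lengths differ")
    if not np.isin(labels, (-1, 1)).all():
        raise DataError("labels must be -1 or +1")
    rows = []
    for cutoff in cutoffs:
        retained, predicted, coverage = cautious_predict(probs, float(cutoff))
        n_ret = int(retained.sum())
        acc = float((predicted[retained] == labels[retained]).mean()) if n_ret else np.nan
        rows.append((float(cutoff), n_ret, coverage, acc))
    return pd.DataFrame(rows, columns=["cutoff", "n_retained", "coverage", "accuracy"])


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2.

    Invariant under strictly increasing transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
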