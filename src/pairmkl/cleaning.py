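"""Sequential training with outlier avoidance for mislabeled link data.

Wrongly labeled training pairs (a nonlink recorded as a link, or vice
versa) act as outliers that distort the decision boundary.  Two sequential
strategies mitigate them, both starting from a small reliable seed set:
the points of each class closest to their class centroid in the composite
feature space.

``sequential_lowest_confidence``
    At each step, predict margins for all unlearnt points and learn the
    one with the smallest |phi| (lowest confidence).  Outliers sit far on
    the wrong side of the boundary, so they are deferred to the end of the
    sequence.  Learning can stop once the margin band is empty — no
    unlearnt point has |phi| <= 1 — because from then on every candidate
    is either a would-be non-support vector (alpha = 0, no effect) or a
    point confidently placed among the opposite class, i.e. a likely
    mislabel.

``random_screen_clean``
    Visit points in random order; before learning a point, predict its
    label with the current calibrated model.  A high-confidence prediction
    that contradicts the recorded label flags the point as a potential
    outlier and it is skipped.  Much cheaper than the margin ordering.

Training is a full exact re-solve per step (results therefore match a
cold re-solve by construction); incremental warm-starting would be an
optimization, not a change in semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import Calibration, fit_sigmoid, predict_proba
from .exceptions import DataError
from .mkl_svm import _clip_psd, _svm_solve, compute_bias

#: Default seeds per class, and default screening confidence threshold.
DEFAULT_SEEDS_PER_CLASS = 10
DEFAULT_CONFIDENCE_THRESHOLD = 0.95


@dataclass
class CleaningTrace:
    """Record of one sequential-cleaning run.

    ``seed_indices``, ``order`` (learned sequence) and the indices in
    ``skipped`` partition the training set.  ``stop_index`` is the
    position in ``order`` at which the empty-margin-band criterion fired
    (== len(order) if it never fired, or for the random-screen strategy,
    which has no stopping rule).  ``test_error_trace`` has one entry per
    model: after the seed fit, then after each learned point.
    """

    seed_indices: np.ndarray
    order: np.ndarray
    skipped: list[tuple[int, float]]
    stop_index: int
    test_error_trace: np.ndarray | None = None
    events: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seed_indices = np.asarray(self.seed_indices, dtype=np.int64)
        self.order = np.asarray(self.order, dtype=np.int64)
        if not 0 <= self.stop_index <= len(self.order):
            raise DataError("stop_index out of range")

    def n_points(self) -> int:
        return len(self.seed_indices) + len(self.order) + len(self.skipped)

    def all_indices(self) -> np.ndarray:
        skip = np.array([i for i, _ in self.skipped], dtype=np.int64)
        return np.concatenate([self.seed_indices, self.order, skip])

    def unlearnt_at_stop(self) -> np.ndarray:
        """Indices not yet learned when the stopping criterion fired."""
        return self.order[self.stop_index:]

    def error_at_stop(self) -> float:
        if self.test_error_trace is None:
            raise DataError("no test error trace recorded")
        return float(self.test_error_trace[self.stop_index])

    def error_at_end(self) -> float:
        if self.test_error_trace is None:
            raise DataError("no test error trace recorded")
        return float(self.test_error_trace[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events,
                            columns=["step", "index", "action", "abs_phi",
                                     "prob", "test_error"])


def _combine(grams, weights) -> np.ndarray:
    if isinstance(grams, np.ndarray) and grams.ndim == 2:
        grams = [grams]
    grams = [np.asarray(g, dtype=float) for g in grams]
    if weights is None:
        weights = np.full(len(grams), 1.0 / len(grams))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(grams):
        raise DataError("weights length does not match number of grams")
    out = np.zeros_like(grams[0])
    for w, g in zip(weights, grams):
        out += w * g
    return out


def cosine_normalize_gram(gram: np.ndarray) -> np.ndarray:
    """Cosine-normalize a pairwise Gram: G_ij / sqrt(G_ii G_jj)."""
    gram = np.asarray(gram, dtype=float)
    d = np.diag(gram)
    if (d <= 0).any():
        raise DataError("cosine normalization needs a strictly positive diagonal")
    inv = 1.0 / np.sqrt(d)
    return gram * np.outer(inv, inv)


def centroid_seeds(gram: np.ndarray, labels, n_per_class: int = DEFAULT_SEEDS_PER_CLASS,
                   cosine: bool = True) -> np.ndarray:
    """Per class, the ``n_per_class`` points closest to the class centroid.

    Distances are computed in the kernel-induced feature space via
    d^2(x) = K(x,x) - (2/n) sum_j K(x,x_j) + (1/n^2) sum_{jk} K(x_j,x_k)
    over same-class members.  Ties break toward the lowest index.

    With ``cosine=True`` (default) the Gram is cosine-normalized first, so
    distances are taken between unit feature vectors.  This matters for
    pairwise kernels whose self-similarity differs systematically between
    links and nonlinks (e.g. the tensor product kernel, where a pair's
    self-similarity is 1 + K(a,b)^2): on the raw Gram that difference
    alone can pull mislabeled pairs toward the wrong class centroid.
    """
    gram = np.asarray(gram, dtype=float)
    if cosine:
        gram = cosine_normalize_gram(gram)
    labels = np.asarray(labels)
    seeds = []
    for cls in (-1, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_per_class:
            raise DataError(f"class {cls:+d} has {len(idx)} members, "
                            f"fewer than n_per_class={n_per_class}")
        sub = gram[np.ix_(idx, idx)]
        n = len(idx)
        d2 = np.diag(sub) - (2.0 / n) * sub.sum(axis=1) + sub.sum() / (n * n)
        picked = idx[np.argsort(d2, kind="stable")[:n_per_class]]
        seeds.append(picked)
    return np.sort(np.concatenate(seeds))


@dataclass
class SequentialResult:
    """Trace plus the model trained on the full learned sequence."""

    trace: CleaningTrace
    alphas: np.ndarray
    bias: float
    learned_indices: np.ndarray


def _test_error(composite_cross, learned, v_full, bias, test_labels) -> float:
    # composite_cross: (n_test, n_train); v_full: alpha*y embedded at learned positions
    phi = composite_cross[:, learned] @ v_full + bias
    pred = np.where(phi >= 0, 1, -1)
    return float((pred != test_labels).mean())


def sequential_lowest_confidence(grams, labels, c: float, seeds,
                                 weights=None, test_grams=None, test_labels=None,
                                 ) -> SequentialResult:
    """Learn unlearnt points in order of increasing |phi|; record the stop point.

    The stopping criterion (margin band empty: min unlearnt |phi| > 1)
    only marks ``stop_index``; learning continues to the end so callers
    can compare the stopped model with the fully trained one.  If test
    Grams and labels are given, held-out error is recorded per step.
    """
    labels = np.asarray(labels)
    composite = _clip_psd(_combine(grams, weights), name="cleaning composite")
    n = len(labels)
    seeds = np.asarray(seeds, dtype=np.int64)
    if np.unique(labels[seeds]).size < 2:
        raise DataError("seed set must contain both classes")
    test_cross = None
    if test_grams is not None:
        test_cross = _combine(test_grams, weights)
        test_labels = np.asarray(test_labels)

    learned = list(seeds)
    unlearnt = sorted(set(range(n)) - set(int(s) for s in seeds))
    order: list[int] = []
    stop_index: int | None = None
    errors: list[float] = []
    events: list[dict] = []

    def refit():
        sub = composite[np.ix_(learned, learned)]
        y_sub = labels[learned]
        alphas, _ = _svm_solve(sub, y_sub, c)
        bias = compute_bias(alphas, y_sub, sub, c)
        return alphas, bias

    alphas, bias = refit()
    if test_cross is not None:
        errors.append(_test_error(test_cross, learned, alphas * labels[learned],
                                  bias, test_labels))
    for step, s in enumerate(seeds):
        events.append({"step": step, "index": int(s), "action": "seed",
                       "abs_phi": np.nan, "prob": np.nan,
                       "test_error": errors[0] if errors else np.nan})

    step = len(seeds)
    while unlearnt:
        v = alphas * labels[learned]
        phi_u = composite[np.ix_(unlearnt, learned)] @ v + bias
        abs_phi = np.abs(phi_u)
        if stop_index is None and abs_phi.min() > 1.0:
            stop_index = len(order)
            events.append({"step": step, "index": -1, "action": "stop",
                           "abs_phi": float(abs_phi.min()), "prob": np.nan,
                           "test_error": errors[-1] if errors else np.nan})
        j = int(np.argmin(abs_phi))  # first minimum; unlearnt ascending -> lowest index
        idx = unlearnt.pop(j)
        order.append(idx)
        learned.append(idx)
        alphas, bias = refit()
        err = np.nan
        if test_cross is not None:
            err = _test_error(test_cross, learned, alphas * labels[learned],
                              bias, test_labels)
            errors.append(err)
        events.append({"step": step, "index": idx, "action": "learn",
                       "abs_phi": float(abs_phi[j]), "prob": np.nan,
                       "test_error": err})
        step += 1

    if stop_index is None:
        stop_index = len(order)
    trace = CleaningTrace(seed_indices=seeds, order=np.array(order, dtype=np.int64),
                          skipped=[], stop_index=stop_index,
                          test_error_trace=(np.array(errors) if errors else None),
                          events=events)
    return SequentialResult(trace=trace, alphas=alphas, bias=bias,
                            learned_indices=np.array(learned, dtype=np.int64))


def refit_at_stop(grams, labels, c: float, trace: CleaningTrace, weights=None,
                  ) -> tuple[np.ndarray, float, np.ndarray]:
    """Re-train on seeds plus the points learned before the stop only."""
    composite = _clip_psd(_combine(grams, weights), name="cleaning composite")
    learned = np.concatenate([trace.seed_indices, trace.order[:trace.stop_index]])
    sub = composite[np.ix_(learned, learned)]
    y_sub = np.asarray(labels)[learned]
    alphas, _ = _svm_solve(sub, y_sub, c)
    bias = compute_bias(alphas, y_sub, sub, c)
    return alphas, bias, learned


def random_screen_clean(grams, labels, c: float, seeds,
                        confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                        seed: int = 0, recalibrate_every: int = 25,
                        weights=None, test_grams=None, test_labels=None,
                        ) -> SequentialResult:
    """Visit points in seeded random order, skipping confident disagreements.

    Before learning a point, its link probability is predicted with the
    current model and calibration; if the confidence max(p, 1-p) reaches
    ``confidence_threshold`` and the predicted label contradicts the
    recorded one, the point is skipped and logged as a potential outlier.
    The calibration is refit every ``recalibrate_every`` learned points.
    """
    if not 0.5 < confidence_threshold <= 1.0:
        raise DataError("confidence_threshold must be in (0.5, 1]")
    labels = np.asarray(labels)
    composite = _clip_psd(_combine(grams, weights), name="cleaning composite")
    n = len(labels)
    seeds = np.asarray(seeds, dtype=np.int64)
    if np.unique(labels[seeds]).size < 2:
        raise DataError("seed set must contain both classes")
    test_cross = None
    if test_grams is not None:
        test_cross = _combine(test_grams, weights)
        test_labels = np.asarray(test_labels)

    rng = np.random.default_rng(seed)
    visit = rng.permutation(np.array(sorted(set(range(n)) - set(int(s) for s in seeds)),
                                     dtype=np.int64))

    learned = list(seeds)
    order: list[int] = []
    skipped: list[tuple[int, float]] = []
    errors: list[float] = []
    events: list[dict] = []

    def refit():
        sub = composite[np.ix_(learned, learned)]
        y_sub = labels[learned]
        alphas, _ = _svm_solve(sub, y_sub, c)
        bias = compute_bias(alphas, y_sub, sub, c)
        return alphas, bias

    def recalibrate(alphas, bias) -> Calibration:
        # calibrate on cross-validated margins within the learned set:
        # training margins are optimistically large and would make the
        # screen overconfident
        idx = np.asarray(learned)
        y_l = labels[idx]
        sub = composite[np.ix_(idx, idx)]
        phi = np.empty(len(idx))
        n_folds = 3
        folds = np.arange(len(idx)) % n_folds
        for f in range(n_folds):
            tr_m, te_m = folds != f, folds == f
            if np.unique(y_l[tr_m]).size < 2:
                tr_m[:] = True
            a_f, _ = _svm_solve(sub[np.ix_(np.flatnonzero(tr_m), np.flatnonzero(tr_m))],
                                y_l[tr_m], c)
            b_f = compute_bias(a_f, y_l[tr_m],
                               sub[np.ix_(np.flatnonzero(tr_m), np.flatnonzero(tr_m))], c)
            phi[te_m] = (sub[np.ix_(np.flatnonzero(te_m), np.flatnonzero(tr_m))]
                         @ (a_f * y_l[tr_m]) + b_f)
        # regularized targets keep the sigmoid from saturating on the small
        # (near-separable) learned sets early in the screen: confidence is
        # then bounded by ~(N+1)/(N+2) and grows with the evidence
        return fit_sigmoid(phi, y_l, platt_targets=True)

    alphas, bias = refit()
    cal = recalibrate(alphas, bias)
    if test_cross is not None:
        errors.append(_test_error(test_cross, learned, alphas * labels[learned],
                                  bias, test_labels))
    for step, s in enumerate(seeds):
        events.append({"step": step, "index": int(s), "action": "seed",
                       "abs_phi": np.nan, "prob": np.nan,
                       "test_error": errors[0] if errors else np.nan})

    since_recal = 0
    for step, idx in enumerate(visit, start=len(seeds)):
        phi_i = float(composite[idx, learned] @ (alphas * labels[learned]) + bias)
        p = float(predict_proba(cal, phi_i))
        predicted = 1 if p >= 0.5 else -1
        confidence = max(p, 1.0 - p)
        if confidence >= confidence_threshold and predicted != labels[idx]:
            skipped.append((int(idx), p))
            events.append({"step": step, "index": int(idx), "action": "skip",
                           "abs_phi": abs(phi_i), "prob": p,
                           "test_error": errors[-1] if errors else np.nan})
            continue
        learned.append(int(idx))
        order.append(int(idx))
        alphas, bias = refit()
        since_recal += 1
        if since_recal >= recalibrate_every:
            cal = recalibrate(alphas, bias)
            since_recal = 0
        err = np.nan
        if test_cross is not None:
            err = _test_error(test_cross, learned, alphas * labels[learned],
                              bias, test_labels)
            errors.append(err)
        events.append({"step": step, "index": int(idx), "action": "learn",
                       "abs_phi": abs(phi_i), "prob": p, "test_error": err})

    trace = CleaningTrace(seed_indices=seeds, order=np.array(order, dtype=np.int64),
                          skipped=skipped, stop_index=len(order),
                          test_error_trace=(np.array(errors) if errors else None),
                          events=events)
    return SequentialResult(trace=trace, alphas=alphas, bias=bias,
                            learned_indices=np.array(learned, dtype=np.int64))
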