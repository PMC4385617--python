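"""Sigmoid calibration of SVM margins into link probabilities.

The margin phi(z) is converted to a posterior via the two-parameter sigmoid

    p(y = +1 | phi) = 1 / (1 + exp(A phi + B)),

with (A, B) chosen to minimize the cross-entropy (negative log likelihood)
of the training labels, using targets t = (y + 1)/2 in {0, 1}.  When large
margins favour the +1 class the fitted slope A is negative, making p
increasing in phi.

The optimizer is a damped (Levenberg-style) Newton iteration on the
two-dimensional cross-entropy surface: the damping factor starts at 1e-3,
is multiplied by 10 on a rejected step and divided by 10 on an accepted
one, so accepted steps never increase the cross-entropy.  Perfectly
separated margins drive |A| to infinity; the fit stops at a configurable
cap and flags the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .exceptions import DataError

#: |A| cap for (near-)separable inputs.
A_CAP = 1e3


@dataclass
class Calibration:
    """Fitted sigmoid parameters plus fit metadata."""

    a: float
    b_sig: float
    n_fit: int = 0
    n_iter: int = 0
    converged: bool = True
    capped: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b_sig)):
            raise DataError("calibration parameters must be finite")


def predict_proba(cal: Calibration, phi) -> np.ndarray:
    """p(y = +1 | phi) = 1/(1 + exp(A phi + B)), numerically stable, in (0, 1)."""
    s = cal.a * np.asarray(phi, dtype=float) + cal.b_sig
    p = expit(-s)
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)


def _cross_entropy(a: float, b: float, phi: np.ndarray, t: np.ndarray) -> float:
    s = a * phi + b
    # NLL = sum t*softplus(s) + (1-t)*softplus(-s)
    return float(np.sum(t * np.logaddexp(0.0, s) + (1.0 - t) * np.logaddexp(0.0, -s)))


def cross_entropy(cal: Calibration, phi, labels) -> float:
    """Cross-entropy of labels under the calibrated probabilities."""
    phi = np.asarray(phi, dtype=float)
    t = (np.asarray(labels) + 1.0) / 2.0
    return _cross_entropy(cal.a, cal.b_sig, phi, t)


def fit_sigmoid(phi, labels, platt_targets: bool = False, max_iter: int = 200,
                grad_tol: float = 1e-8, a_cap: float = A_CAP) -> Calibration:
    """Fit (A, B) by damped-Newton minimization of the cross-entropy.

    Parameters
    ----------
    phi : array
        Decision values (margins).
    labels : array of -1/+1
        Link labels; targets are t = (y+1)/2.
    platt_targets : bool
        If true, use the regularized targets (N+ + 1)/(N+ + 2) and
        1/(N- + 2) instead of raw {0, 1}; off by default.
    """
    phi = np.asarray(phi, dtype=float)
    labels = np.asarray(labels)
    if phi.shape != labels.shape:
        raise DataError("phi and labels lengths differ")
    if not np.isin(labels, (-1, 1)).all():
        raise DataError("labels must be -1 or +1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present to fit the sigmoid")

    t = (labels + 1.0) / 2.0
    if platt_targets:
        t = np.where(labels == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    a, b = 0.0, float(np.log(n_neg / n_pos))
    nll = _cross_entropy(a, b, phi, t)
    damping = 1e-3
    converged = False
    capped = False
    it = 0
    for it in range(1, max_iter + 1):
        s = a * phi + b
        sig = expit(s)  # = 1 - p
        g_s = sig - (1.0 - t)
        grad = np.array([g_s @ phi, g_s.sum()])
        if np.abs(grad).max() <= grad_tol:
            converged = True
            break
        w = sig * (1.0 - sig)
        H = np.array([[w @ (phi * phi), w @ phi],
                      [w @ phi, w.sum()]])
        accepted = False
        for _ in range(50):
            try:
                delta = np.linalg.solve(H + damping * np.eye(2), -grad)
            except np.linalg.LinAlgError:
                damping *= 10.0
                continue
            a_new, b_new = a + delta[0], b + delta[1]
            nll_new = _cross_entropy(a_new, b_new, phi, t)
            if np.isfinite(nll_new) and nll_new <= nll:
                a, b, nll = a_new, b_new, nll_new
                damping = max(damping / 10.0, 1e-12)
                accepted = True
                break
            damping *= 10.0
        if not accepted:
            converged = True  # no improving step at numerical precision
            break
        if abs(a) > a_cap:
            a = float(np.sign(a) * a_cap)
            capped = True
            break
    return Calibration(a=a, b_sig=b, n_fit=len(phi), n_iter=it,
                       converged=converged, capped=capped)
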