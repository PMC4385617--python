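"""Simplex-constrained multiple kernel learning with an SVM dual.

The composite kernel is a convex combination of base pairwise Grams,
K_bar = sum_l lambda_l K_l with lambda on the probability simplex, and the
weights are learned jointly with the SVM dual coefficients:

    min_lambda  max_alpha  1'alpha - 1/2 (alpha y)' K_bar(lambda) (alpha y)
    s.t. sum(lambda) = 1, lambda >= 0, 0 <= alpha <= C, alpha'y = 0

The outer problem is solved by reduced-gradient descent on lambda with an
exact SVM solve per iterate (SimpleMKL style); the inner solves delegate
to libsvm via scikit-learn with a precomputed kernel.  Each learned
weight lambda_l measures the relative informativeness of base kernel l;
uniform weighting is the special case lambda_l = 1/p, so the optimized
objective can never exceed the uniform-weight objective.

The SVM bias uses the midpoint rule over bias-free decision values,

    b = -1/2 [ max_{y_i=-1} f0(x_i) + min_{y_i=+1} f0(x_i) ],

which centres the decision boundary between the most advanced negative
point and the least advanced positive point.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .calibration import Calibration
from .exceptions import ConvergenceError, DataError
from .node_kernels import NodeKernel, PSDWarning, align_kernels, normalize_kernel
from .pairwise_kernels import BaseKernelSpec, PairSet, PairwiseKernelKind, build_pairwise_gram

logger = logging.getLogger(__name__)

#: Weights below this are zeroed (and lambda renormalized) after convergence.
WEIGHT_FLOOR = 1e-4

#: Inner SVM solver tolerance (libsvm KKT violation bound).
SVM_TOL = 1e-8


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if not np.isin(labels, (-1, 1)).all():
        raise DataError("labels must be -1 or +1")
    if np.unique(labels).size < 2:
        raise DataError("both classes must be present")
    return labels


def _clip_psd(gram: np.ndarray, name: str = "gram") -> np.ndarray:
    """Clip negative eigenvalues at zero if the matrix is indefinite beyond tolerance."""
    gram = np.asarray(gram, dtype=float)
    sym = (gram + gram.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(sym)
    ref = eigvals[-1] if eigvals[-1] > 0 else 1.0
    if eigvals[0] >= -1e-8 * ref:
        return sym
    warnings.warn(
        f"{name}: indefinite beyond tolerance (min eigenvalue {eigvals[0]:.3e}); "
        "clipping negative eigenvalues at zero", PSDWarning, stacklevel=3)
    clipped = eigvecs @ (np.clip(eigvals, 0.0, None)[:, None] * eigvecs.T)
    return (clipped + clipped.T) / 2.0


def _svm_solve(gram: np.ndarray, labels: np.ndarray, c: float) -> tuple[np.ndarray, float]:
    """Exact soft-margin SVM dual solve on a precomputed Gram.

    Returns the full alpha vector (0 <= alpha <= C, alpha'y = 0) and the
    dual objective 1'alpha - 1/2 (alpha y)' K (alpha y).
    """
    clf = SVC(C=c, kernel="precomputed", tol=SVM_TOL, shrinking=True, cache_size=256)
    clf.fit(gram, labels)
    alpha = np.zeros(len(labels))
    alpha[clf.support_] = np.abs(clf.dual_coef_[0])
    np.clip(alpha, 0.0, c, out=alpha)
    v = alpha * labels
    objective = float(alpha.sum() - 0.5 * v @ gram @ v)
    return alpha, objective


def compute_bias(alphas: np.ndarray, labels: np.ndarray, gram: np.ndarray,
                 c: float | None = None) -> float:
    """Midpoint-rule bias from bias-free training decision values.

    b = -1/2 [max_{y=-1} f0 + min_{y=+1} f0], where the max/min run over
    points whose alpha is strictly below the box bound C (for such points
    the KKT conditions pin y(f0 + b) >= 1, with equality at support
    vectors, so the midpoint recovers the exact bias; margin violators at
    alpha = C satisfy only the reverse inequality and would corrupt it).
    On separable data no alpha sits at the bound and this reduces to the
    plain midpoint over each full class.  A class whose every point is at
    the bound falls back to all its members.
    """
    labels = np.asarray(labels)
    f0 = gram @ (alphas * labels)
    free = np.ones(len(labels), dtype=bool)
    if c is not None:
        free = alphas < c * (1.0 - 1e-6)
    neg = labels == -1
    pos = labels == +1
    if not neg.any() or not pos.any():
        raise DataError("both classes must be present to compute the bias")
    neg_f = f0[neg & free] if (neg & free).any() else f0[neg]
    pos_f = f0[pos & free] if (pos & free).any() else f0[pos]
    return float(-0.5 * (neg_f.max() + pos_f.min()))


def train_svm(gram: np.ndarray, labels, c: float) -> tuple[np.ndarray, float, float]:
    """Train a soft-margin SVM on a precomputed (pairwise) Gram matrix.

    Returns ``(alphas, bias, objective)``.  An indefinite Gram (beyond the
    PSD tolerance) is convexified by eigenvalue clipping with a warning.
    """
    labels = _check_labels(labels)
    gram = np.asarray(gram, dtype=float)
    if gram.shape != (len(labels), len(labels)):
        raise DataError(f"gram shape {gram.shape} does not match {len(labels)} labels")
    if c <= 0:
        raise DataError("C must be positive")
    gram = _clip_psd(gram)
    alphas, objective = _svm_solve(gram, labels, c)
    bias = compute_bias(alphas, labels, gram, c)
    return alphas, bias, objective


def uniform_composite(base_grams: list[np.ndarray]) -> np.ndarray:
    """Unweighted mean of the base Grams (lambda_l = 1/p)."""
    if not base_grams:
        raise DataError("need at least one base gram")
    shape = np.asarray(base_grams[0]).shape
    for g in base_grams[1:]:
        if np.asarray(g).shape != shape:
            raise DataError("base gram shape mismatch")
    return np.mean(np.stack([np.asarray(g, dtype=float) for g in base_grams]), axis=0)


@dataclass
class MKLResult:
    """Output of :func:`mkl_train`."""

    weights: np.ndarray
    alphas: np.ndarray
    bias: float
    objective: float
    gap: float
    n_iter: int
    converged: bool
    #: one record per outer iteration: objective, relative gap, active weights
    history: list[dict] = field(default_factory=list)


def mkl_train(base_grams: list[np.ndarray], labels, c: float = 1.0,
              tol: float = 1e-4, max_iter: int = 200,
              weight_floor: float = WEIGHT_FLOOR) -> MKLResult:
    """Reduced-gradient MKL on the simplex with exact SVM solves per iterate.

    Convergence: relative duality gap <= ``tol`` or lambda step <= 1e-6.
    After convergence, weights below ``weight_floor`` are zeroed, lambda is
    renormalized, and the SVM is re-solved on the sparsified composite.

    Raises
    ------
    ConvergenceError
        If neither criterion is met within ``max_iter`` outer iterations
        (the error carries the last relative gap).
    """
    labels = _check_labels(labels)
    if not base_grams:
        raise DataError("need at least one base gram")
    n = len(labels)
    grams = []
    for i, g in enumerate(base_grams):
        g = np.asarray(g, dtype=float)
        if g.shape != (n, n):
            raise DataError(f"base gram {i}: shape {g.shape} does not match {n} labels")
        grams.append(_clip_psd(g, name=f"base gram {i}"))
    p = len(grams)

    lam = np.full(p, 1.0 / p)

    def composite(weights: np.ndarray) -> np.ndarray:
        out = np.zeros((n, n))
        for w, g in zip(weights, grams):
            if w > 0:
                out += w * g
        return out

    alpha, J = _svm_solve(composite(lam), labels, c)
    history: list[dict] = []
    converged = False
    rel_gap = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        v = alpha * labels
        S = np.array([0.5 * v @ g @ v for g in grams])
        gap = float(S.max() - S @ lam)
        rel_gap = gap / max(abs(J), 1e-12)
        history.append({
            "iteration": it, "objective": J, "rel_gap": rel_gap,
            "weights": lam.copy(),
        })
        logger.info("mkl iter %d: objective=%.10g rel_gap=%.3e active=%s",
                    it, J, rel_gap,
                    [f"{i}:{w:.3f}" for i, w in enumerate(lam) if w > 1e-6])
        if rel_gap <= tol:
            converged = True
            break

        grad = -S  # dJ/dlambda_l at the optimal alpha
        mu = int(np.argmax(lam))
        red = grad - grad[mu]
        D = np.where((lam > 0) | (red < 0), -red, 0.0)
        D[mu] = 0.0
        D[mu] = -D.sum()
        if np.abs(D).max() <= 1e-14:
            converged = True  # stationary point of the reduced gradient
            break
        neg = D < 0
        gamma_max = float(np.min(-lam[neg] / D[neg]))
        gamma, accepted = gamma_max, False
        while gamma > 1e-14:
            lam_new = np.clip(lam + gamma * D, 0.0, None)
            lam_new /= lam_new.sum()
            alpha_new, J_new = _svm_solve(composite(lam_new), labels, c)
            if J_new < J:
                step = float(np.abs(lam_new - lam).max())
                lam, alpha, J = lam_new, alpha_new, J_new
                accepted = True
                if step <= 1e-6:
                    converged = True
                break
            gamma *= 0.5
        if not accepted:
            # no descent achievable at solver precision
            converged = True
            break
        if converged:
            break

    if not converged:
        raise ConvergenceError(
            f"MKL did not converge in {max_iter} iterations "
            f"(last relative gap {rel_gap:.3e})", last_gap=rel_gap)

    # sparsify and renormalize, then re-solve so alpha matches the final composite
    lam[lam < weight_floor] = 0.0
    if lam.sum() <= 0:
        lam = np.full(p, 1.0 / p)
    lam /= lam.sum()
    final = composite(lam)
    alpha, J = _svm_solve(final, labels, c)
    bias = compute_bias(alpha, labels, final, c)
    return MKLResult(weights=lam, alphas=alpha, bias=bias, objective=J,
                     gap=rel_gap, n_iter=it, converged=True, history=history)


@dataclass
class CompositeModel:
    """A trained MKL link predictor.

    ``train_pairs`` indexes into ``node_ids``, the node universe shared by
    all base kernels at training time.
    """

    base_specs: list[BaseKernelSpec]
    weights: np.ndarray
    alphas: np.ndarray
    bias: float
    box_bound: float
    train_pairs: PairSet
    node_ids: list[str]
    objective: float
    normalize: bool = True
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.alphas = np.asarray(self.alphas, dtype=float)
        if len(self.base_specs) != len(self.weights):
            raise DataError("weights length does not match base specs")
        if abs(self.weights.sum() - 1.0) > 1e-9 or (self.weights < -1e-12).any():
            raise DataError("weights must lie on the simplex")
        if self.train_pairs.labels is None:
            raise DataError("train_pairs must be labeled")
        if len(self.alphas) != len(self.train_pairs):
            raise DataError("alphas length does not match training pairs")
        c = self.box_bound
        if c <= 0:
            raise DataError("box bound C must be positive")
        if (self.alphas < -1e-9 * c).any() or (self.alphas > c * (1 + 1e-9)).any():
            raise DataError("alphas violate the box constraint [0, C]")
        bal = float(self.alphas @ self.train_pairs.labels)
        if abs(bal) > 1e-6 * c * max(1.0, len(self.alphas)):
            raise DataError(f"alpha'y = {bal:.3e} violates the equality constraint")


def _prepare_kernels(kernels: list[NodeKernel], normalize: bool) -> dict[str, NodeKernel]:
    kernels = align_kernels(kernels)
    if normalize:
        kernels = [normalize_kernel(k) for k in kernels]
    store = {k.name: k for k in kernels}
    if len(store) != len(kernels):
        raise DataError("kernel names are not unique")
    return store


def build_base_grams(kernels: list[NodeKernel], specs: list[BaseKernelSpec],
                     rows: PairSet, cols: PairSet | None = None,
                     normalize: bool = True) -> list[np.ndarray]:
    """Assemble one pairwise Gram per base spec over a shared node universe."""
    store = _prepare_kernels(kernels, normalize)
    grams = []
    for spec in specs:
        if spec.kernel_name not in store:
            raise DataError(f"base spec references unknown kernel '{spec.kernel_name}'")
        grams.append(build_pairwise_gram(spec.kind, store[spec.kernel_name], rows, cols))
    return grams


def fit_composite(kernels: list[NodeKernel], specs: list[BaseKernelSpec],
                  pairs: PairSet, c: float = 1.0, normalize: bool = True,
                  tol: float = 1e-4, max_iter: int = 200) -> CompositeModel:
    """Train a composite MKL model from node kernels and a labeled pair set."""
    if pairs.labels is None:
        raise DataError("training pairs must be labeled")
    store = _prepare_kernels(kernels, normalize)
    node_ids = list(next(iter(store.values())).node_ids)
    grams = []
    for spec in specs:
        if spec.kernel_name not in store:
            raise DataError(f"base spec references unknown kernel '{spec.kernel_name}'")
        grams.append(build_pairwise_gram(spec.kind, store[spec.kernel_name], pairs))
    result = mkl_train(grams, pairs.labels, c=c, tol=tol, max_iter=max_iter)
    return CompositeModel(base_specs=list(specs), weights=result.weights,
                          alphas=result.alphas, bias=result.bias, box_bound=c,
                          train_pairs=pairs, node_ids=node_ids,
                          objective=result.objective, normalize=normalize)


def decision_function(model: CompositeModel, test_pairs: PairSet,
                      kernels: list[NodeKernel]) -> np.ndarray:
    """Margins phi(z) = sum_j alpha_j y_j K_bar(train_j, z) + b for new pairs."""
    store = _prepare_kernels(kernels, model.normalize)
    ref_ids = next(iter(store.values())).node_ids
    if ref_ids != model.node_ids:
        if set(ref_ids) != set(model.node_ids):
            raise DataError("kernels cover a different node set than the model")
        # re-align the store to the model's node order
        order = {nid: i for i, nid in enumerate(ref_ids)}
        idx = [order[nid] for nid in model.node_ids]
        store = {
            name: NodeKernel(node_ids=list(model.node_ids),
                             matrix=k.matrix[np.ix_(idx, idx)], name=name)
            for name, k in store.items()
        }
    if test_pairs.pairs.size and test_pairs.pairs.max() >= len(model.node_ids):
        raise DataError("test pair index out of range for the model's node universe")
    v = model.alphas * model.train_pairs.labels
    phi = np.full(len(test_pairs), model.bias)
    for w, spec in zip(model.weights, model.base_specs):
        if w <= 0:
            continue
        if spec.kernel_name not in store:
            raise DataError(f"model requires kernel '{spec.kernel_name}'")
        cross = build_pairwise_gram(spec.kind, store[spec.kernel_name],
                                    rows=test_pairs, cols=model.train_pairs)
        phi += w * (cross @ v)
    return phi


def predict_labels(phi: np.ndarray) -> np.ndarray:
    """sign(phi) with sign(0) mapped to +1."""
    return np.where(np.asarray(phi) >= 0, 1, -1)


def cross_validate(base_grams: list[np.ndarray], labels, c: float = 1.0,
                   n_folds: int = 5, seed: int = 0, uniform_baseline: bool = True,
                   tol: float = 1e-4) -> dict:
    """Stratified k-fold evaluation of MKL (and optionally uniform weights).

    Returns per-fold accuracy/AUC records, the per-fold learned weights,
    and out-of-fold margins aligned with the input order (suitable for
    fitting a held-out calibration).
    """
    from sklearn.model_selection import StratifiedKFold

    from .prediction import auc as _auc

    labels = _check_labels(labels)
    n = len(labels)
    grams = [np.asarray(g, dtype=float) for g in base_grams]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof_phi = np.full(n, np.nan)
    folds, weights_per_fold = [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
        sub = [g[np.ix_(tr, tr)] for g in grams]
        res = mkl_train(sub, labels[tr], c=c, tol=tol)
        weights_per_fold.append(res.weights)
        v = res.alphas * labels[tr]
        cross = np.zeros((len(te), len(tr)))
        for w, g in zip(res.weights, grams):
            if w > 0:
                cross += w * g[np.ix_(te, tr)]
        phi = cross @ v + res.bias
        oof_phi[te] = phi
        rec = {
            "fold": fold,
            "n_train": len(tr), "n_test": len(te),
            "accuracy_weighted": float((predict_labels(phi) == labels[te]).mean()),
            "auc_weighted": _auc(phi, labels[te]),
        }
        if uniform_baseline:
            uni = uniform_composite(sub)
            alphas_u, bias_u, _ = train_svm(uni, labels[tr], c)
            cross_u = uniform_composite([g[np.ix_(te, tr)] for g in grams])
            phi_u = cross_u @ (alphas_u * labels[tr]) + bias_u
            rec["accuracy_uniform"] = float((predict_labels(phi_u) == labels[te]).mean())
            rec["auc_uniform"] = _auc(phi_u, labels[te])
        folds.append(rec)
    return {"folds": folds, "oof_phi": oof_phi,
            "weights_per_fold": weights_per_fold}


# ---------------------------------------------------------------------------
# model persistence (structured text, round-trip exact at 17 significant digits)

def save_model(model: CompositeModel, path) -> None:
    doc = {
        "format": "pairmkl-model",
        "version": 1,
        "c": model.box_bound,
        "normalize": model.normalize,
        "base_specs": [{"kind": s.kind.value, "kernel": s.kernel_name}
                       for s in model.base_specs],
        "weights": list(model.weights),
        "node_ids": list(model.node_ids),
        "train_pairs": [[model.node_ids[a], model.node_ids[b]]
                        for a, b in model.train_pairs.pairs],
        "train_labels": [int(y) for y in model.train_pairs.labels],
        "alphas": list(model.alphas),
        "bias": model.bias,
        "objective": model.objective,
        "calibration": None if model.calibration is None else {
            "a": model.calibration.a,
            "b": model.calibration.b_sig,
            "n": model.calibration.n_fit,
            "iterations": model.calibration.n_iter,
            "converged": model.calibration.converged,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path) -> CompositeModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "pairmkl-model":
        raise DataError(f"{path}: not a pairmkl model file")
    node_ids = [str(i) for i in doc["node_ids"]]
    index = {nid: i for i, nid in enumerate(node_ids)}
    try:
        pairs = np.array([[index[a], index[b]] for a, b in doc["train_pairs"]])
    except KeyError as exc:
        raise DataError(f"{path}: training pair references unknown node {exc}") from exc
    cal = doc.get("calibration")
    calibration = None
    if cal is not None:
        calibration = Calibration(a=float(cal["a"]), b_sig=float(cal["b"]),
                                  n_fit=int(cal["n"]), n_iter=int(cal["iterations"]),
                                  converged=bool(cal["converged"]))
    return CompositeModel(
        base_specs=[BaseKernelSpec(PairwiseKernelKind(s["kind"]), s["kernel"])
                    for s in doc["base_specs"]],
        weights=np.array(doc["weights"], dtype=float),
        alphas=np.array(doc["alphas"], dtype=float),
        bias=float(doc["bias"]),
        box_bound=float(doc["c"]),
        train_pairs=PairSet(pairs, np.array(doc["train_labels"], dtype=np.int64)),
        node_ids=node_ids,
        objective=float(doc["objective"]),
        normalize=bool(doc["normalize"]),
        calibration=calibration,
    )
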