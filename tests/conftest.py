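"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pairmkl import NodeKernel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd(rng, n, rank=None, jitter=0.0):
    """Random PSD matrix as A A' (construction guarantees PSD)."""
    rank = rank or n
    A = rng.normal(size=(n, rank))
    K = A @ A.T
    if jitter:
        K += jitter * np.eye(n)
    return K


def linear_kernel_from_features(X, name="lin"):
    """NodeKernel wrapping the linear kernel of explicit feature vectors."""
    ids = [f"n{i}" for i in range(len(X))]
    return NodeKernel(node_ids=ids, matrix=X @ X.T, name=name)


# ---------------------------------------------------------------------------
# explicit feature-space oracles for the pairwise kernels (linear base kernel)
# These construct the pair feature vector literally and take inner products,
# independently of the Gram-assembly code under test.

def oracle_p1(X, pa, pb):
    """Symmetrized tensor-product feature map."""
    a, b = X[pa[0]], X[pa[1]]
    c, d = X[pb[0]], X[pb[1]]
    fa = np.outer(a, b) + np.outer(b, a)
    fb = np.outer(c, d) + np.outer(d, c)
    return 0.5 * float((fa * fb).sum())


def oracle_p2(X, pa, pb):
    """Summed-vector feature map."""
    u = X[pa[0]] + X[pa[1]]
    v = X[pb[0]] + X[pb[1]]
    return float(u @ v)


def oracle_p3(X, pa, pb):
    """Squared inner product of difference vectors (tensor of differences)."""
    u = X[pa[0]] - X[pa[1]]
    v = X[pb[0]] - X[pb[1]]
    return float((u @ v) ** 2)


def oracle_p4(X, pa, pb):
    """Cosine similarity of difference vectors."""
    u = X[pa[0]] - X[pa[1]]
    v = X[pb[0]] - X[pb[1]]
    return float((u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def oracle_p5(K, pa, pb):
    """Direct indicator-gated sum on node indices."""
    a, b = pa
    c, d = pb
    return float(K[a, c] * (b == d) + K[b, d] * (a == c)
                 + K[a, d] * (b == c) + K[b, c] * (a == d))


def qp_oracle_alphas(K, y, C):
    """Reference soft-margin SVM dual solve via generic QP solvers.

    Tries SLSQP and falls back to trust-constr (SLSQP occasionally aborts
    its line search on flat directions).
    """
    from scipy.optimize import LinearConstraint, minimize

    y = np.asarray(y, dtype=float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    fun = lambda a: 0.5 * a @ Q @ a - a.sum()
    jac = lambda a: Q @ a - 1.0
    x0 = np.full(n, min(C, 1.0) / 2)
    res = minimize(fun, x0, jac=jac, method="SLSQP", bounds=[(0.0, C)] * n,
                   constraints=[{"type": "eq", "fun": lambda a: a @ y,
                                 "jac": lambda a: y}],
                   options={"maxiter": 2000, "ftol": 1e-14})
    if not res.success:
        res = minimize(fun, x0, jac=jac, hess=lambda a: Q, method="trust-constr",
                       bounds=[(0.0, C)] * n,
                       constraints=[LinearConstraint(y[None, :], 0.0, 0.0)],
                       options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-14})
    assert res.success, res.message
    return res.x
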