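"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from specdebias.spectral import SpectralTransform


def dense_q(t: SpectralTransform) -> np.ndarray:
    """Dense n-by-n reconstruction of Q = U S U^T (+ complement identity).

    Brute-force oracle; the library never materialises this matrix.
    """
    U, S = t.U, t.S_diag
    Q = (U * S) @ U.T
    if t.complement == "identity":
        Q += np.eye(t.n) - U @ U.T
    return Q


def weighted_lasso_objective(QX, QY, beta, lam, w) -> float:
    n = QX.shape[0]
    r = QY - QX @ beta
    return 0.5 * float(r @ r) / n + lam * float(np.sum(w * np.abs(beta)))


def prox_gradient_lasso(QX, QY, lam, w, n_iter=200_000, tol=1e-12):
    """Independent proximal-gradient (ISTA) solver for the weighted lasso.

    Deliberately naive: fixed step 1/L with L the largest eigenvalue of
    QX^T QX / n, soft-thresholding at lam * w * step.
    """
    n, p = QX.shape
    L = np.linalg.norm(QX, 2) ** 2 / n
    step = 1.0 / L
    thresh = lam * w * step
    beta = np.zeros(p)
    for _ in range(n_iter):
        grad = -QX.T @ (QY - QX @ beta) / n
        z = beta - step * grad
        new = np.sign(z) * np.maximum(np.abs(z) - thresh, 0.0)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


def slsqp_precision_row(X, t, j, mu):
    """Generic convex-programming oracle for the row program.

    Minimises theta' (X' Q^4 X) theta subject to the ell-infinity
    constraint, via scipy SLSQP on a dense reconstruction of Q.  Only
    sensible for small p.
    """
    from scipy.optimize import minimize

    n, p = X.shape
    Q = dense_q(t)
    QX = Q @ X
    M = X.T @ np.linalg.matrix_power(Q, 4) @ X
    Sig = QX.T @ QX / n
    ej = np.zeros(p)
    ej[j] = 1.0

    cons = [{"type": "ineq",
             "fun": lambda th, i=i, sgn=sgn:
                 mu - sgn * (ej[i] - Sig[i] @ th)}
            for i in range(p) for sgn in (1.0, -1.0)]
    res = minimize(lambda th: th @ M @ th, x0=np.zeros(p), method="SLSQP",
                   constraints=cons,
                   options={"maxiter": 2000, "ftol": 1e-14})
    if not res.success:
        raise RuntimeError(f"SLSQP failed: {res.message}")
    return res.x, float(res.fun)


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
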