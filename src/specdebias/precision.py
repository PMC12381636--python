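"""Approximate inverse covariance by convex programs, and the debiased estimator.

Stage two corrects the ell_1-penalty bias of the deconfounded lasso by
inverting its Karush-Kuhn-Tucker conditions.  With Sigma_hat = (QX)^T QX / n,
the estimator

    beta_hat = beta_dec + Theta_hat (QX)^T (QY - QX beta_dec) / n

needs an approximate inverse Theta_hat of Sigma_hat.  Row j of Theta_hat
solves the convex program

    minimise    theta^T (X^T Q^4 X) theta
    subject to  || e_j - Sigma_hat theta ||_inf <= mu,

which trades the stochastic variance of the correction (the objective)
against the residual bias (the constraint).  No sparsity of the precision
matrix is assumed.  If a program is infeasible the whole matrix falls back
to the identity (a per-row fallback is available as a non-default option).

Solver
------
Writing X = U Lambda V^T and Q = U S U^T (+ identity off span(U)), the row
program reduces to a minimum-norm problem whose Lagrange dual is the
ell_1-regularised quadratic

    minimise_v  v^T (X^T X) v / (4 n^2)  -  v_j  +  mu ||v||_1,

independent of Q; the primal solution is recovered as
theta = V S^{-2} V^T v / (2n) (restricted to the positive singular values).
The dual is solved exactly by an active-set ("feature-sign") method:
coordinates enter at their most violated subgradient condition, the
quadratic is solved exactly on the active set, and segments are backtracked
to the first sign crossing.  On convergence the recovered theta is feasible
and the duality gap is checked directly.  Infeasibility (possible whenever
e_j is far from the row space of X in ell_inf) is certified by a linear
program minimising the constraint residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .lasso import DeconfoundedFit
from .spectral import RANK_FLOOR, SpectralTransform

__all__ = ["PrecisionApprox", "DebiasedEstimate", "SolverError",
           "default_mu", "solve_precision_row", "assemble_precision",
           "debias", "min_linf_residual"]

_FEAS_TOL = 1e-6        # slack allowed on the ell_inf constraint
_GAP_TOL = 1e-8         # relative duality-gap tolerance
_MAX_ITER = 20_000


class SolverError(RuntimeError):
    """The active-set solver failed on a certified-feasible program."""


@dataclass(frozen=True)
class PrecisionApprox:
    """Approximate inverse Theta of the empirical covariance of QX.

    Rows not in ``solved_coords`` were never optimised (single-coordinate
    mode) and are identity rows.  ``feasible`` flags each solved row;
    ``fallback_identity`` is True when the global fallback replaced Theta
    by the identity because some solved row was infeasible.
    """

    Theta: np.ndarray
    mu: float
    feasible: dict[int, bool]
    fallback_identity: bool
    solved_coords: tuple[int, ...]


@dataclass(frozen=True)
class DebiasedEstimate:
    """Stage-two output: beta_hat = beta_dec + correction."""

    beta_hat: np.ndarray
    beta_dec: np.ndarray
    correction: np.ndarray
    residual_norm: float


def default_mu(n: int, p: int, form: str = "sqrt") -> float:
    """Default constraint tolerance for the row programs.

    ``"sqrt"`` gives 0.5 * sqrt(log(p)/n), the scale at which the programs
    are feasible with high probability in the regimes targeted here;
    ``"raw"`` gives 0.5 * log(p)/n, which is typically below the smallest
    attainable residual when n < p and then triggers the identity fallback.
    """
    if n < 2 or p < 2:
        raise ValueError("need n >= 2 and p >= 2")
    if form == "sqrt":
        return 0.5 * float(np.sqrt(np.log(p) / n))
    if form == "raw":
        return 0.5 * float(np.log(p)) / n
    raise ValueError("form must be 'sqrt' or 'raw'")


def _dual_active_set(G: np.ndarray, j: int, mu: float, n: int,
                     max_iter: int = _MAX_ITER
                     ) -> tuple[np.ndarray, bool, int]:
    """Minimise v'Gv/(4n^2) - v_j + mu||v||_1 exactly.

    Returns (v, converged, iterations).  Non-convergence within the
    iteration budget is the signal used to trigger LP certification of
    infeasibility (the dual is unbounded below iff the primal constraint
    set is empty).
    """
    p = G.shape[0]
    c2 = 2.0 * n * n
    v = np.zeros(p)
    Gv = np.zeros(p)
    active: list[int] = []
    signs: dict[int, float] = {}
    cap = min(n, p) + 5  # active set larger than rank(G) signals divergence
    for it in range(max_iter):
        g = Gv / c2
        g[j] -= 1.0
        viol = np.abs(g) - mu
        if active:
            viol[active] = 0.0
        i_new = int(np.argmax(viol))
        if viol[i_new] > 1e-10:
            active.append(i_new)
            signs[i_new] = -np.sign(g[i_new])
        else:
            if not active:
                return v, True, it
            ga = g[active] + mu * np.array([signs[i] for i in active])
            if np.max(np.abs(ga)) <= 1e-9 * max(1.0, float(np.abs(g).max())):
                return v, True, it
        # exact solve on the active set, backtracking over sign crossings
        while True:
            A = np.array(active)
            s = np.array([signs[i] for i in A])
            GA = G[np.ix_(A, A)] / c2
            rhs = -mu * s
            rhs[A == j] += 1.0
            try:
                vA_new = np.linalg.solve(GA, rhs)
            except np.linalg.LinAlgError:
                vA_new = np.linalg.lstsq(GA, rhs, rcond=None)[0]
            vA_old = v[A]
            d = vA_new - vA_old
            with np.errstate(divide="ignore", invalid="ignore"):
                tc = -vA_old / d
            tc[(tc <= 1e-12) | (tc > 1.0) | ~np.isfinite(tc)] = np.inf
            tmin = float(tc.min()) if tc.size else np.inf
            if tmin > 1.0 - 1e-12:
                v[A] = vA_new
                Gv = G[:, A] @ vA_new
                break
            kdrop = int(np.argmin(tc))
            v[A] = vA_old + tmin * d
            idrop = active[kdrop]
            v[idrop] = 0.0
            active.pop(kdrop)
            signs.pop(idrop)
            if not active:
                Gv = np.zeros(p)
                break
            Aa = np.array(active)
            Gv = G[:, Aa] @ v[Aa]
        if len(active) > cap:
            return v, False, it
    return v, False, max_iter


def min_linf_residual(G: np.ndarray, j: int, n: int) -> float:
    """Smallest attainable ||e_j - Sigma theta||_inf over theta (an LP).

    Because range(Sigma_hat) equals the row space of X for every positive
    definite Q, the Gram matrix G = X^T X can stand in for Sigma_hat here.
    """
    p = G.shape[0]
    Sig = G / n
    ej = np.zeros(p)
    ej[j] = 1.0
    A = np.vstack([np.hstack([-Sig, -np.ones((p, 1))]),
                   np.hstack([Sig, -np.ones((p, 1))])])
    b = np.concatenate([-ej, ej])
    c = np.zeros(p + 1)
    c[-1] = 1.0
    res = linprog(c, A_ub=A, b_ub=b,
                  bounds=[(None, None)] * p + [(0, None)], method="highs")
    if not res.success:
        raise SolverError(f"feasibility LP failed for row {j}: {res.message}")
    return float(res.fun)


def _recover_theta(t: SpectralTransform, v: np.ndarray) -> np.ndarray:
    """Map the dual solution back to theta = V S^-2 V^T v / (2n), using only
    the numerically positive singular values."""
    floor = RANK_FLOOR * max(t.singular_values[0], 1.0)
    pos = t.singular_values > floor
    Vr = t.V[:, pos]
    return Vr @ ((t.S_diag[pos] ** -2.0) * (Vr.T @ v)) / (2.0 * t.n)


def solve_precision_row(X: np.ndarray, t: SpectralTransform, j: int,
                        mu: float, gram: np.ndarray | None = None,
                        dual_cache: dict | None = None
                        ) -> tuple[np.ndarray | None, bool]:
    """Solve the row-j convex program.

    Returns ``(theta_j, True)`` at the optimum, or ``(None, False)`` when
    the constraint set is certified empty.  ``gram`` may carry a
    precomputed X^T X.  Because the dual problem does not involve Q, a
    ``dual_cache`` dict may be shared across transforms of the same X to
    reuse dual solutions (keyed by (j, mu)).

    Raises :class:`SolverError` if the solver stalls on a program the LP
    certifies as feasible.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if not 0 <= j < p:
        raise IndexError(f"coordinate {j} out of range [0, {p})")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if (t.n, t.p) != (n, p):
        raise ValueError("transform dimensions do not match X")
    G = X.T @ X if gram is None else gram
    key = (j, mu)
    if dual_cache is not None and key in dual_cache:
        v, converged = dual_cache[key]
    else:
        v, converged, _ = _dual_active_set(G, j, mu, n)
        if not converged and min_linf_residual(G, j, n) <= mu + _FEAS_TOL:
            raise SolverError(f"active-set solver stalled on feasible row {j}")
        if dual_cache is not None:
            dual_cache[key] = (v, converged)
    if not converged:
        return None, False
    theta = _recover_theta(t, v)
    # certify: constraint satisfied and duality gap closed
    resid = -G @ v / (2.0 * n * n)
    resid[j] += 1.0
    primal = float(v @ G @ v) / (4.0 * n * n)
    gap = 2.0 * primal - v[j] + mu * float(np.abs(v).sum())
    if np.max(np.abs(resid)) > mu + _FEAS_TOL or gap > _GAP_TOL * max(1.0, primal):
        raise SolverError(f"row {j}: solution failed certification "
                          f"(resid {np.max(np.abs(resid)):.2e}, gap {gap:.2e})")
    return theta, True


def assemble_precision(X: np.ndarray, t: SpectralTransform, mu: float,
                       coords: list[int] | None = None,
                       fallback: str = "global",
                       gram: np.ndarray | None = None,
                       dual_cache: dict | None = None) -> PrecisionApprox:
    """Solve the row programs for the requested coordinates.

    ``coords=None`` solves all p rows.  Under ``fallback="global"`` (the
    default) any infeasible row replaces the whole matrix by the identity;
    ``fallback="row"`` substitutes the identity row only.
    """
    if fallback not in ("global", "row"):
        raise ValueError("fallback must be 'global' or 'row'")
    X = np.asarray(X, float)
    n, p = X.shape
    coords = list(range(p)) if coords is None else list(coords)
    G = X.T @ X if gram is None else gram
    Theta = np.eye(p)
    feasible: dict[int, bool] = {}
    for j in coords:
        theta, ok = solve_precision_row(X, t, j, mu, gram=G,
                                        dual_cache=dual_cache)
        feasible[j] = ok
        if ok:
            Theta[j] = theta
        elif fallback == "global":
            return PrecisionApprox(Theta=np.eye(p), mu=mu, feasible=feasible,
                                   fallback_identity=True,
                                   solved_coords=tuple(coords))
    return PrecisionApprox(Theta=Theta, mu=mu, feasible=feasible,
                           fallback_identity=False,
                           solved_coords=tuple(coords))


def debias(fit: DeconfoundedFit, prec: PrecisionApprox,
           QX: np.ndarray, QY: np.ndarray) -> DebiasedEstimate:
    """Form beta_hat = beta_dec + Theta (QX)^T (QY - QX beta_dec) / n."""
    QX = np.asarray(QX, float)
    QY = np.asarray(QY, float).ravel()
    n, p = QX.shape
    if fit.beta_dec.shape[0] != p or prec.Theta.shape != (p, p):
        raise ValueError("dimension mismatch between fit, precision and QX")
    resid = QY - QX @ fit.beta_dec
    correction = prec.Theta @ (QX.T @ resid) / n
    return DebiasedEstimate(beta_hat=fit.beta_dec + correction,
                            beta_dec=fit.beta_dec, correction=correction,
                            residual_norm=float(np.linalg.norm(resid)))
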