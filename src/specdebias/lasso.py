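"""Deconfounded weighted lasso: stage one of the two-step estimator.

Minimises

    (1/2n) ||QY - QX b||_2^2  +  lambda * sum_j w_j |b_j|,

with per-column penalty weights w_j = ||QX_j||_2 / sqrt(n) (the root mean
square of column j), so that lambda is comparable across sample sizes and
the problem is equivalent to a unit-weight lasso on column-rescaled data.
The regularisation parameter is chosen by K-fold cross-validation on the
transformed rows over a log-spaced grid descending from the full-shrinkage
threshold lambda_max.

The grid is walked from large to small lambda in warm-started chunks and
abandoned early once the mean CV error has clearly passed its minimum;
this leaves the selected lambda unchanged on problems with an interior CV
minimum while avoiding the dense, expensive tail of the path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

__all__ = ["DeconfoundedFit", "fit_deconfounded", "cross_validate_lambda",
           "lambda_max", "penalty_weights", "kkt_residuals"]

# final-fit coordinate-descent tolerance; loose path tolerance for CV only
_FIT_TOL = 1e-8
_PATH_TOL = 1e-3
_PATH_MAX_ITER = 500


@dataclass(frozen=True)
class DeconfoundedFit:
    """Weighted-lasso fit on spectrally transformed data.

    ``beta_dec`` is on the original covariate scale.  ``cv_curve`` is a
    DataFrame with columns (lambda, mean_cv_error); rows the early-stopped
    search never evaluated are absent.
    """

    beta_dec: np.ndarray
    lam: float
    penalty_weights: np.ndarray
    cv_folds: int
    cv_curve: pd.DataFrame | None = None
    seed: int | None = None


def penalty_weights(QX: np.ndarray, scale: str = "rms") -> np.ndarray:
    """Per-column penalty weights: ``"rms"`` gives ||QX_j||/sqrt(n), ``"raw"``
    the plain column norm ||QX_j||."""
    norms = np.linalg.norm(QX, axis=0)
    if scale == "rms":
        return norms / np.sqrt(QX.shape[0])
    if scale == "raw":
        return norms
    raise ValueError("scale must be 'rms' or 'raw'")


def lambda_max(QX: np.ndarray, QY: np.ndarray, weights: np.ndarray) -> float:
    """Smallest lambda at which the weighted-lasso solution is exactly zero."""
    n = QX.shape[0]
    w = np.where(weights > 0, weights, np.inf)
    return float(np.max(np.abs(QX.T @ QY) / (n * w)))


def _check_inputs(QX: np.ndarray, QY: np.ndarray) -> None:
    if not (np.all(np.isfinite(QX)) and np.all(np.isfinite(QY))):
        raise ValueError("non-finite values in transformed data")
    if QX.shape[0] != QY.shape[0]:
        raise ValueError("QX and QY disagree on the number of rows")
    if not np.any(QX):
        raise ValueError("design matrix is identically zero")


def cross_validate_lambda(QX: np.ndarray, QY: np.ndarray, grid: np.ndarray,
                          folds: int = 10, seed: int = 0,
                          chunk: int = 10, patience: int = 15,
                          rel_margin: float = 0.02,
                          path_tol: float = _PATH_TOL,
                          path_max_iter: int = _PATH_MAX_ITER,
                          ) -> tuple[float, pd.DataFrame]:
    """Choose lambda by K-fold CV over a descending grid.

    Folds are a seeded random partition of the transformed rows.  Returns
    the lambda minimising the mean held-out squared error (ties go to the
    larger lambda) and the evaluated part of the CV curve.  The walk down
    the grid stops once the current error exceeds the running minimum by
    ``rel_margin`` and the minimum is at least ``patience`` grid points
    behind; set ``patience >= len(grid)`` to force a full sweep.
    """
    QX = np.asarray(QX, float)
    QY = np.asarray(QY, float).ravel()
    _check_inputs(QX, QY)
    n = QX.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    grid = np.sort(np.asarray(grid, float))[::-1]
    n_grid = grid.shape[0]
    splits = list(KFold(folds, shuffle=True, random_state=seed).split(QX))
    warm = [None] * folds
    mean_err = np.full(n_grid, np.nan)
    done = 0
    while done < n_grid:
        hi = min(done + chunk, n_grid)
        block = grid[done:hi]
        acc = np.zeros(hi - done)
        for f, (tr, te) in enumerate(splits):
            kw = {} if warm[f] is None else {"coef_init": warm[f].copy()}
            with warnings.catch_warnings():
                # the loose path tolerance is deliberate (selection only)
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, coefs, _ = lasso_path(QX[tr], QY[tr], alphas=block,
                                         tol=path_tol,
                                         max_iter=path_max_iter, **kw)
            warm[f] = coefs[:, -1]
            acc += np.mean((QY[te][:, None] - QX[te] @ coefs) ** 2, axis=0)
        mean_err[done:hi] = acc / folds
        done = hi
        cur = mean_err[:done]
        imin = int(np.argmin(cur))
        if (done - 1 - imin >= patience
                and cur[done - 1] > cur[imin] * (1.0 + rel_margin)):
            break
    imin = int(np.nanargmin(mean_err[:done]))
    curve = pd.DataFrame({"lambda": grid[:done], "mean_cv_error": mean_err[:done]})
    return float(grid[imin]), curve


def fit_deconfounded(QX: np.ndarray, QY: np.ndarray,
                     lam: float | str = "cv", cv_folds: int = 10,
                     seed: int = 0, weight_scale: str = "rms",
                     n_lambdas: int = 100, lambda_min_ratio: float = 1e-3,
                     grid: np.ndarray | None = None) -> DeconfoundedFit:
    """Fit the deconfounded weighted lasso.

    ``lam`` may be a nonnegative number or ``"cv"``, in which case a
    log-spaced grid of ``n_lambdas`` values from lambda_max down to
    ``lambda_min_ratio * lambda_max`` is searched by ``cv_folds``-fold CV.
    Columns of QX with zero norm are excluded from the fit and get
    coefficient zero.
    """
    QX = np.asarray(QX, float)
    QY = np.asarray(QY, float).ravel()
    _check_inputs(QX, QY)
    n, p = QX.shape
    w = penalty_weights(QX, weight_scale)
    live = w > 0
    Xs = QX[:, live] / w[live]

    curve = None
    if isinstance(lam, str):
        if lam != "cv":
            raise ValueError("lam must be a number or 'cv'")
        if grid is None:
            lmax = lambda_max(QX, QY, w)
            grid = np.logspace(np.log10(lmax),
                               np.log10(lmax * lambda_min_ratio), n_lambdas)
        lam, curve = cross_validate_lambda(Xs, QY, grid, folds=cv_folds,
                                           seed=seed)
    elif lam < 0:
        raise ValueError("lam must be nonnegative")

    beta = np.zeros(p)
    if lam == 0:
        # unpenalised limit: minimum-norm least squares on the live columns
        beta[live], *_ = np.linalg.lstsq(Xs, QY, rcond=None)
    else:
        model = Lasso(alpha=lam, fit_intercept=False, tol=_FIT_TOL,
                      max_iter=200_000)
        model.fit(Xs, QY)
        beta[live] = model.coef_
    beta[live] /= w[live]
    return DeconfoundedFit(beta_dec=beta, lam=float(lam), penalty_weights=w,
                           cv_folds=cv_folds, cv_curve=curve, seed=seed)


def kkt_residuals(QX: np.ndarray, QY: np.ndarray, fit: DeconfoundedFit
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stationarity diagnostics of the weighted-lasso optimum.

    Returns ``(grad, bound)`` with grad_j = -(QX_j)^T (QY - QX b)/n and
    bound_j = lambda * w_j.  At an exact optimum |grad_j| = bound_j for
    active coordinates and |grad_j| <= bound_j for inactive ones.
    """
    n = QX.shape[0]
    grad = -QX.T @ (QY - QX @ fit.beta_dec) / n
    return grad, fit.lam * fit.penalty_weights
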