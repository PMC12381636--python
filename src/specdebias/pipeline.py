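"""End-to-end deconfounded-and-debiased estimation.

Chains the three stages — spectral transform, cross-validated weighted
lasso, KKT-inversion debiasing — behind one call.  The plain debiased
lasso (no deconfounding) is the same pipeline with the shrinkage diagonal
forced to ones (``shrink=False``).

When only a few coordinates are of interest (``coords``), only the
corresponding rows of the precision program are solved; coordinate j of
the debiased estimator depends on row j alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import RegressionData
from .lasso import DeconfoundedFit, fit_deconfounded
from .precision import (PrecisionApprox, assemble_precision, debias,
                        default_mu)
from .spectral import (DegenerateRankError, SpectralTransform,
                       apply_transform, compute_spectral_transform)

__all__ = ["PipelineResult", "fit_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    """Everything the two-step fit produced."""

    beta_hat: np.ndarray
    beta_dec: np.ndarray
    correction: np.ndarray
    lam: float
    mu: float
    rho: float
    transform: SpectralTransform
    fit: DeconfoundedFit
    precision: PrecisionApprox
    coords: tuple[int, ...]

    @property
    def fallback_identity(self) -> bool:
        return self.precision.fallback_identity


def fit_pipeline(data: RegressionData | tuple, *, rho: float = 0.5,
                 lam: float | str = "cv", mu: float | str = "auto",
                 mu_form: str = "sqrt", coords: list[int] | str = "all",
                 shrink: bool = True, cv_folds: int = 10, seed: int = 0,
                 fallback: str = "global", weight_scale: str = "rms",
                 complement: str = "identity",
                 _shared: dict | None = None) -> PipelineResult:
    """Run the full two-step estimator.

    Parameters mirror the stage functions: ``rho`` the spectral quantile,
    ``lam`` the lasso penalty (``"cv"`` for 10-fold cross-validation),
    ``mu`` the precision-program tolerance (``"auto"`` for the default
    formula), ``coords`` the coordinates to debias (``"all"`` or a list).
    ``shrink=False`` disables the spectral shrinkage (Q = I), giving the
    plain KKT-inversion debiased lasso.

    ``_shared`` is an internal cache reused across method variants on the
    same dataset (SVD, Gram matrix and dual solutions are Q-independent).
    """
    if isinstance(data, tuple):
        data = RegressionData(X=data[0], Y=data[1])
    X, Y = data.X, data.Y
    n, p = X.shape
    cache = _shared if _shared is not None else {}

    if "transform" not in cache:
        try:
            cache["transform"] = compute_spectral_transform(
                data, rho=rho, complement=complement, shrink=True)
        except DegenerateRankError:
            if shrink:
                raise
            cache["transform"] = compute_spectral_transform(
                data, rho=rho, complement=complement, shrink=False)
        cache["gram"] = X.T @ X
        cache["dual"] = {}
    t_full: SpectralTransform = cache["transform"]
    if shrink:
        t = t_full
    else:
        from dataclasses import replace
        t = replace(t_full, S_diag=np.ones(t_full.m))
    QX, QY = apply_transform(t, data)

    fit = fit_deconfounded(QX, QY, lam=lam, cv_folds=cv_folds, seed=seed,
                           weight_scale=weight_scale)

    mu_val = default_mu(n, p, form=mu_form) \
        if isinstance(mu, str) and mu == "auto" else float(mu)
    coord_list = list(range(p)) \
        if isinstance(coords, str) and coords == "all" else list(coords)
    # the dual solutions are Q-free: share them across shrink variants
    prec = assemble_precision(X, t, mu_val, coords=coord_list,
                              fallback=fallback, gram=cache["gram"],
                              dual_cache=cache["dual"])

    est = debias(fit, prec, QX, QY)
    return PipelineResult(beta_hat=est.beta_hat, beta_dec=est.beta_dec,
                          correction=est.correction, lam=fit.lam, mu=mu_val,
                          rho=rho, transform=t, fit=fit, precision=prec,
                          coords=tuple(coord_list))
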