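"""Pairs-bootstrap percentile confidence intervals for single coefficients.

Rows of (X, Y) are resampled with replacement and the full two-step
pipeline — spectral transform, cross-validated lasso, single-coordinate
debiasing — is re-run on every resample.  Pairs resampling is used because
hidden confounding lives in the rows; residual resampling would destroy
the very structure the estimator corrects for.  Intervals are percentile
intervals with linearly interpolated order statistics (numpy's default,
"type 7" in the classical taxonomy), which makes them bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import RegressionData
from .pipeline import fit_pipeline

__all__ = ["BootstrapResult", "bootstrap_ci"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate, replicate draws and percentile interval."""

    coord: int
    point_estimate: float
    replicates: np.ndarray
    level: float
    ci_lower: float
    ci_upper: float
    B: int
    seed: int
    n_failed: int = 0


def bootstrap_ci(data: RegressionData, coord: int, B: int = 500,
                 level: float = 0.95, seed: int = 0,
                 skip_errors: bool = True, refit_lambda: bool = True,
                 **pipeline_kw) -> BootstrapResult:
    """Percentile bootstrap CI for one coefficient of the debiased estimator.

    Each of the ``B`` replicates resamples the n rows with replacement and
    re-runs the complete pipeline (cross-validation and the precision
    program included).  Extra keyword arguments are passed to
    :func:`specdebias.pipeline.fit_pipeline`.

    ``refit_lambda=False`` freezes the penalty level chosen on the
    original sample and reuses it in every replicate — a cheaper variant
    that skips the per-replicate cross-validation.

    With ``skip_errors`` (default) a replicate whose pipeline raises is
    logged and redrawn, so the returned vector always holds ``B`` finite
    values; set it False to propagate the first failure.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    n = data.n
    pipeline_kw.setdefault("coords", [coord])

    full = fit_pipeline(data, seed=seed, **pipeline_kw)
    point = float(full.beta_hat[coord])
    if not refit_lambda:
        pipeline_kw["lam"] = full.lam

    reps: list[float] = []
    n_failed = 0
    b = 0
    while len(reps) < B:
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(coord, b))
        b += 1
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, size=n)
        sub = RegressionData(X=data.X[idx], Y=data.Y[idx])
        cv_seed = int(ss.generate_state(2)[1] % (2 ** 31))
        try:
            est = fit_pipeline(sub, seed=cv_seed, **pipeline_kw)
        except Exception:
            if not skip_errors:
                raise
            n_failed += 1
            log.exception("bootstrap replicate %d failed; redrawing", b - 1)
            if n_failed > B:
                raise RuntimeError("too many failed bootstrap replicates")
            continue
        reps.append(float(est.beta_hat[coord]))
    replicates = np.array(reps)
    alpha = 1.0 - level
    lo, hi = np.quantile(replicates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(coord=coord, point_estimate=point,
                           replicates=replicates, level=level,
                           ci_lower=float(lo), ci_upper=float(hi),
                           B=B, seed=seed, n_failed=n_failed)
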