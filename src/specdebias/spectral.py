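"""Spectral transformation for deconfounding.

Hidden confounders that act on many covariates at once inflate the leading
singular values of the design matrix X.  The spectral transformation

    Q = U S U^T,   S_ii = Lambda_k / Lambda_i  for i <= k,  1 otherwise,

built from the SVD X = U Lambda V^T, shrinks the top k = floor(rho * m)
singular values down to the rho-quantile singular value Lambda_k
(m = min(n, p)).  Regressing QY on QX then attenuates the confounder-driven
perturbation while leaving the bulk of the spectrum untouched.  The largest
singular value of QX equals Lambda_k by construction.

When n > p the column span of U does not cover R^n.  Q as written would
annihilate the component of Y orthogonal to span(U); this module instead
lets Q act as the identity there (``complement="identity"``), so that an
all-ones shrinkage diagonal recovers Q = I exactly.  The literal reading
(``complement="drop"``) is available for comparison.

Q is never materialised as a dense n-by-n matrix here: QX and QY are
computed from the factors.  Dense reconstructions live only in test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .data import RegressionData

__all__ = ["SpectralTransform", "DegenerateRankError",
           "compute_spectral_transform", "apply_transform"]

#: singular values below RANK_FLOOR * largest are treated as zero
RANK_FLOOR = 1e-12


class DegenerateRankError(ValueError):
    """The quantile singular value Lambda_k is numerically zero."""


@dataclass(frozen=True)
class SpectralTransform:
    """SVD factors of X together with the shrinkage diagonal defining Q.

    Attributes
    ----------
    U, V : ndarray
        Left (n x m) and right (p x m) singular vectors of X.
    singular_values : ndarray of shape (m,)
        Nonincreasing singular values Lambda_i.
    S_diag : ndarray of shape (m,)
        Shrinkage factors, Lambda_k/Lambda_i for i <= k and 1 otherwise;
        all entries lie in (0, 1].
    rho : float
        Quantile parameter in (0, 1).
    k : int
        Shrinkage index floor(rho * m) (1-based count of shrunk values).
    complement : str
        How Q acts on the orthogonal complement of span(U) when n > m:
        ``"identity"`` (default) or ``"drop"``.
    """

    U: np.ndarray
    V: np.ndarray
    singular_values: np.ndarray
    S_diag: np.ndarray
    rho: float
    k: int
    complement: str = "identity"

    @property
    def m(self) -> int:
        return self.singular_values.shape[0]

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def p(self) -> int:
        return self.V.shape[0]

    @property
    def rank(self) -> int:
        floor = RANK_FLOOR * max(self.singular_values[0], 1.0)
        return int(np.sum(self.singular_values > floor))


def compute_spectral_transform(data: RegressionData | np.ndarray,
                               rho: float = 0.5,
                               complement: str = "identity",
                               shrink: bool = True) -> SpectralTransform:
    """Construct the spectral transformation from the SVD of X.

    Parameters
    ----------
    data : RegressionData or ndarray
        The design matrix (or the container holding it).
    rho : float in (0, 1)
        Quantile parameter; floor(rho * m) leading singular values are
        shrunk to the rho-quantile singular value.  Default 0.5.
    complement : {"identity", "drop"}
        Behaviour of Q on the orthogonal complement of span(U) (only
        relevant for n > p).
    shrink : bool
        If False the shrinkage diagonal is forced to all ones, so Q = I.
        This is the plain debiased-lasso special case used as a comparator.

    Raises
    ------
    ValueError
        If rho is outside (0,1) or floor(rho*m) < 1.
    DegenerateRankError
        If Lambda_k is numerically zero (rank below the quantile index).
    """
    X = data.X if isinstance(data, RegressionData) else np.asarray(data, float)
    if complement not in ("identity", "drop"):
        raise ValueError("complement must be 'identity' or 'drop'")
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (0, 1), got {rho}")
    n, p = X.shape
    m = min(n, p)
    k = int(np.floor(rho * m))
    U, s, Vt = linalg.svd(X, full_matrices=False)
    S = np.ones(m)
    if shrink:
        if k < 1:
            raise ValueError(
                f"floor(rho*m) = {k} < 1: rho={rho} too small for m={m}")
        if s[k - 1] <= RANK_FLOOR * max(s[0], 1.0):
            raise DegenerateRankError(
                f"quantile singular value Lambda_{k} = {s[k-1]:.3e} is "
                "numerically zero; cannot shrink to it")
        S[:k] = s[k - 1] / s[:k]
    return SpectralTransform(U=U, V=Vt.T, singular_values=s, S_diag=S,
                             rho=rho, k=k, complement=complement)


def apply_transform(t: SpectralTransform,
                    data: RegressionData | np.ndarray | tuple
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Apply Q to the data the transform was computed from.

    Returns ``(QX, QY)``.  QX is computed as U diag(S * Lambda) V^T, which
    is exact because the columns of X lie in span(U).  QY keeps the
    component of Y orthogonal to span(U) untouched under the default
    complement convention (and drops it under ``"drop"``).
    """
    if isinstance(data, RegressionData):
        X, Y = data.X, data.Y
    elif isinstance(data, tuple):
        X, Y = data
    else:
        raise TypeError("data must be RegressionData or an (X, Y) tuple")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float).ravel()
    if X.shape != (t.n, t.p) or Y.shape[0] != t.n:
        raise ValueError(
            f"dimension mismatch: transform is for ({t.n}, {t.p}), "
            f"got X {X.shape}, Y {Y.shape}")
    QX = (t.U * (t.S_diag * t.singular_values)) @ t.V.T
    UtY = t.U.T @ Y
    QY = (t.U * t.S_diag) @ UtY
    if t.complement == "identity":
        QY = QY + (Y - t.U @ UtY)
    return QX, QY
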