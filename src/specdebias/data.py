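"""Observed-data container and delimited-text loading.

The package operates on a numeric design matrix ``X`` (n samples by p
covariates) and a numeric response vector ``Y``.  :class:`RegressionData`
bundles the pair with basic sanity checks; :func:`load_xy` reads the common
CSV/TSV layouts (response in a named column of the same file, or in a
separate single-column file).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RegressionData", "load_xy", "standardize"]


@dataclass(frozen=True)
class RegressionData:
    """An (X, Y) regression sample.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Covariate matrix.  Must be finite with n >= 2, p >= 1.
    Y : ndarray of shape (n,)
        Response vector.
    standardized : bool
        True when each column of ``X`` has (sample) mean 0 and standard
        deviation 1 and ``Y`` has mean 0.  Set by :func:`standardize`.
    columns : tuple of str, optional
        Covariate names carried along for reporting.
    """

    X: np.ndarray
    Y: np.ndarray
    standardized: bool = False
    columns: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError(f"X must be 2-dimensional, got shape {X.shape}")
        n, p = X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if Y.shape[0] != n:
            raise ValueError(f"X has {n} rows but Y has length {Y.shape[0]}")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
            raise ValueError("X and Y must be finite (no NaN/inf)")
        if self.columns is not None and len(self.columns) != p:
            raise ValueError("columns must have one name per covariate")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if self.standardized:
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            if (np.abs(mu).max() > 1e-8 or np.abs(sd - 1.0).max() > 1e-8
                    or abs(Y.mean()) > 1e-8):
                raise ValueError("standardized=True but data are not standardized")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def standardize(data: RegressionData) -> RegressionData:
    """Center and scale each covariate to mean 0, sd 1; center the response.

    Columns with zero variance are left at zero after centering.
    """
    X = data.X - data.X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = X / sd
    Y = data.Y - data.Y.mean()
    return replace(data, X=X, Y=Y, standardized=True)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    # header-less numeric files: first row parsed as header yields numeric names
    try:
        [float(c) for c in df.columns]
    except (TypeError, ValueError):
        return df
    return pd.read_csv(path, sep=sep, header=None)


def load_xy(x_path: str | Path, y_path: str | Path | None = None,
            response: str | None = None) -> RegressionData:
    """Load (X, Y) from delimited text.

    Either ``y_path`` points to a single-column file holding the response,
    or ``response`` names the response column inside ``x_path``.
    """
    dfx = _read_table(x_path)
    if response is not None:
        if response not in dfx.columns:
            raise KeyError(f"response column {response!r} not found")
        Y = dfx[response].to_numpy(dtype=float)
        dfx = dfx.drop(columns=[response])
    elif y_path is not None:
        dfy = _read_table(y_path)
        if dfy.shape[1] != 1:
            raise ValueError("response file must have exactly one column")
        Y = dfy.iloc[:, 0].to_numpy(dtype=float)
    else:
        raise ValueError("provide either y_path or response=<column name>")
    cols = tuple(str(c) for c in dfx.columns)
    return RegressionData(X=dfx.to_numpy(dtype=float), Y=Y, columns=cols)
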