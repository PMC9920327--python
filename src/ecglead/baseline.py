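"""Linear-regression lead transformation via QR factorization.

The classical comparison method: each derived lead is a least-squares
linear combination of leads II, V2, V6 (plus an intercept, on by
default — real recordings carry residual baseline offsets).  The
solution is computed from the thin QR factorization of the
intercept-augmented design matrix, so residuals are orthogonal to the
design columns by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .signal_io import INPUT_LEADS, TARGET_LEADS


class RankDeficiencyError(np.linalg.LinAlgError):
    """The design matrix is (numerically) rank deficient."""


class LinearLeadRegressor(RegressorMixin, BaseEstimator):
    """Least-squares map from the 3 input leads to the 12 derived leads.

    Parameters
    ----------
    intercept : bool, default True
        Include a constant column in the design.

    Attributes
    ----------
    coef_ : ndarray, shape (4, 12) with intercept (3, 12 without)
        Rows: [intercept,] II, V2, V6; columns follow the canonical
        target-lead order.
    fitted_on_ : tuple of str
        Record / patient identifiers the transform was fit on.
    """

    def __init__(self, intercept: bool = True):
        self.intercept = intercept

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(INPUT_LEADS):
            raise ValueError(f"X must be (n, {len(INPUT_LEADS)})")
        if self.intercept:
            return np.column_stack([np.ones(len(X)), X])
        return X

    def fit(self, X: np.ndarray, Y: np.ndarray,
            fitted_on: tuple[str, ...] = ()) -> "LinearLeadRegressor":
        A = self._design(X)
        Y = np.asarray(Y, dtype=np.float64)
        if len(A) != len(Y):
            raise ValueError("X and Y must have equal row counts")
        if len(A) <= A.shape[1]:
            raise ValueError(f"need more than {A.shape[1]} samples")
        Q, R = np.linalg.qr(A)
        diag = np.abs(np.diag(R))
        tol = max(A.shape) * np.finfo(np.float64).eps * diag.max()
        bad = np.nonzero(diag < tol)[0]
        if bad.size:
            names = (["intercept", *INPUT_LEADS] if self.intercept
                     else list(INPUT_LEADS))
            raise RankDeficiencyError(
                f"design column {names[bad[0]]!r} is collinear")
        from scipy.linalg import solve_triangular
        self.coef_ = solve_triangular(R, Q.T @ Y, lower=False)
        self.fitted_on_ = tuple(fitted_on)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._design(X) @ self.coef_

    def to_csv(self, path) -> None:
        check_is_fitted(self, "coef_")
        index = (["intercept", *INPUT_LEADS] if self.intercept
                 else list(INPUT_LEADS))
        pd.DataFrame(self.coef_, index=index,
                     columns=list(TARGET_LEADS)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "LinearLeadRegressor":
        df = pd.read_csv(path, index_col=0)
        est = cls(intercept="intercept" in df.index)
        est.coef_ = df.to_numpy(dtype=np.float64)
        est.fitted_on_ = ()
        return est


def fit_linear(X: np.ndarray, Y: np.ndarray,
               intercept: bool = True) -> LinearLeadRegressor:
    """Functional wrapper: fit the QR least-squares lead transform."""
    return LinearLeadRegressor(intercept=intercept).fit(X, Y)


def predict_linear(transform: LinearLeadRegressor, X: np.ndarray) -> np.ndarray:
    """Apply a fitted transform to (n, 3) input-lead samples."""
    return transform.predict(X)
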