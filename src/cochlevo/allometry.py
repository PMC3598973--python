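"""Allometric ordinary least squares with prediction intervals and outlier classes.

The canonical use is the log-log scaling of basilar-membrane length on the
cube root of body mass across a reference set of species (a caller-supplied
mask, e.g. placental mammals excluding bats and whales), followed by
classification of every species against the 95% prediction interval of that
reference line: points above the upper interval are relatively elongated,
points below relatively short.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import SingularDesignError

__all__ = [
    "AllometricRegression",
    "RegressionFit",
    "fit_ols",
    "prediction_interval",
    "classify_by_interval",
]


def _design(X, add_intercept: bool) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    return X


@dataclass
class RegressionFit:
    """OLS results sufficient to recompute predictions and prediction intervals.

    ``params`` are ordered intercept first (when fitted with an intercept),
    then one slope per predictor column.  ``xtx_inv`` is (X'X)^-1 on the full
    design including the intercept column, which is all that is needed for
    leverage and hence interval computation.
    """

    params: np.ndarray
    resid_std_error: float
    df_resid: int
    rsquared: float
    fvalue: float
    f_pvalue: float
    nobs: int
    xtx_inv: np.ndarray
    param_names: list
    bse: np.ndarray = field(default=None)
    has_intercept: bool = True

    # -- prediction ------------------------------------------------------
    def _row(self, x0) -> np.ndarray:
        x0 = np.atleast_2d(np.asarray(x0, dtype=float))
        if self.has_intercept:
            if x0.shape[1] == len(self.params) - 1:
                x0 = np.column_stack([np.ones(len(x0)), x0])
        if x0.shape[1] != len(self.params):
            raise ValueError(
                f"x0 has {x0.shape[1]} columns, fit expects "
                f"{len(self.params) - int(self.has_intercept)} predictors")
        return x0

    def predict(self, x0) -> np.ndarray:
        return self._row(x0) @ self.params

    def leverage(self, x0) -> np.ndarray:
        rows = self._row(x0)
        return np.einsum("ij,jk,ik->i", rows, self.xtx_inv, rows)

    def prediction_interval(self, x0, level: float = 0.95):
        """(lower, upper) bounds of the level-% prediction interval for a new
        observation at predictor values ``x0``."""
        if not 0 < level < 1:
            raise ValueError(f"level must be in (0, 1), got {level}")
        if self.df_resid < 1:
            raise ValueError("prediction interval requires df_resid >= 1")
        yhat = self.predict(x0)
        if self.resid_std_error <= 1e-10 * (1.0 + float(np.max(np.abs(yhat)))):
            warnings.warn("degenerate fit (zero residual error); "
                          "prediction interval has width 0", stacklevel=2)
            return yhat.copy(), yhat.copy()
        tcrit = scipy.stats.t.ppf(0.5 + level / 2, self.df_resid)
        half = tcrit * self.resid_std_error * np.sqrt(1.0 + self.leverage(x0))
        return yhat - half, yhat + half

    def classify(self, x, y, labels=None, level: float = 0.95) -> pd.Series:
        """Classify labelled points as 'above' / 'within' / 'below' their
        prediction interval.  The partition is exhaustive and exclusive."""
        y = np.asarray(y, dtype=float)
        lower, upper = self.prediction_interval(x, level=level)
        eps = 1e-9 * (1.0 + np.abs(y))  # points numerically on a bound count as within
        cls = np.where(y > upper + eps, "above",
                       np.where(y < lower - eps, "below", "within"))
        if labels is None:
            labels = np.arange(len(y))
        return pd.Series(cls, index=pd.Index(labels, name="label"), name="class")

    def summary(self) -> str:
        lines = [
            "Ordinary least squares allometric fit",
            f"  n = {self.nobs}, df_resid = {self.df_resid}",
            f"  R^2 = {self.rsquared:.4f}, "
            f"F = {self.fvalue:.3f}, p = {self.f_pvalue:.3g}",
            f"  residual std. error = {self.resid_std_error:.4f}",
            "  coefficients:",
        ]
        for name, b, se in zip(self.param_names, self.params,
                               self.bse if self.bse is not None else self.params * np.nan):
            lines.append(f"    {name:<20s} {b:>10.4f}  (se {se:.4f})")
        return "\n".join(lines)


class AllometricRegression:
    """OLS model ``y ~ X`` (intercept added by default).

    Parameters
    ----------
    y : response vector (typically log10 membrane length, mm).
    X : predictor vector/matrix (typically log10 mass^(1/3), g); multiple
        columns give a multiple regression.
    mask : optional boolean reference-set mask — only rows where mask is True
        enter the fit (e.g. non-echolocating placentals); classification can
        then be applied to all rows.
    """

    def __init__(self, y, X, add_intercept: bool = True, mask=None,
                 param_names=None):
        y = np.asarray(y, dtype=float)
        design = _design(X, add_intercept)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            y, design = y[mask], design[mask]
        if len(y) != len(design):
            raise ValueError("y and X have different lengths")
        n, p = design.shape
        if n <= p:
            raise SingularDesignError(f"need n > p, got n={n}, p={p}")
        if np.linalg.matrix_rank(design) < p:
            raise SingularDesignError(
                "design matrix is rank deficient (collinear or constant predictor)")
        self.y, self.design, self.add_intercept = y, design, add_intercept
        if param_names is None:
            param_names = (["intercept"] if add_intercept else []) + [
                f"x{i}" for i in range(p - int(add_intercept))]
        self.param_names = list(param_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, predictors,
                       mask=None) -> "AllometricRegression":
        predictors = [predictors] if isinstance(predictors, str) else list(predictors)
        return cls(df[response].to_numpy(float),
                   df[predictors].to_numpy(float),
                   mask=mask, param_names=["intercept"] + predictors)

    def fit(self) -> RegressionFit:
        res = sm.OLS(self.y, self.design).fit()
        p = self.design.shape[1]
        # statsmodels reports centred R^2 when an intercept is present
        return RegressionFit(
            params=np.asarray(res.params, dtype=float),
            resid_std_error=float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0,
            df_resid=int(res.df_resid),
            rsquared=float(res.rsquared),
            fvalue=float(res.fvalue) if p > 1 else float("nan"),
            f_pvalue=float(res.f_pvalue) if p > 1 else float("nan"),
            nobs=int(res.nobs),
            xtx_inv=np.linalg.inv(self.design.T @ self.design),
            param_names=self.param_names,
            bse=np.asarray(res.bse, dtype=float),
            has_intercept=self.add_intercept,
        )


# ---------------------------------------------------------------------------
# thin functional surface
# ---------------------------------------------------------------------------

def fit_ols(y, X, add_intercept: bool = True, mask=None) -> RegressionFit:
    """Fit ``y ~ X`` by OLS; see :class:`AllometricRegression`."""
    return AllometricRegression(y, X, add_intercept=add_intercept, mask=mask).fit()


def prediction_interval(fit: RegressionFit, x0, level: float = 0.95):
    return fit.prediction_interval(x0, level=level)


def classify_by_interval(fit: RegressionFit, x, y, labels=None,
                         level: float = 0.95) -> pd.Series:
    return fit.classify(x, y, labels=labels, level=level)
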