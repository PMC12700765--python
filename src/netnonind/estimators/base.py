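"""Shared estimator contract.

Every correction strategy is a scikit-learn style estimator: hyperparameters
and network context go to the constructor, ``fit(X, y)`` consumes the single
predictor trait and the outcome trait, and the fitted object exposes the
slope, its standard error, the test statistic, and a two-sided p-value as
trailing-underscore attributes.  ``fit_result()`` packages those into the
uniform :class:`RegressionFit` record used by the Monte-Carlo harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["RegressionFit", "DegenerateFitError", "NetworkRegressor"]


class DegenerateFitError(ValueError):
    """Raised when a fit is impossible (e.g. constant predictor)."""


@dataclass(frozen=True)
class RegressionFit:
    """Uniform summary of one fitted correction strategy.

    ``slope`` is always the coefficient on the predictor trait; ``df`` is
    ``None`` for methods tested with a normal (z) reference distribution.
    ``flags`` records degeneracies and fallbacks; a clean fit has none.
    """

    method: str
    slope: float
    se: float
    statistic: float
    p_value: float
    df: float | None
    n_used: int
    extras: dict[str, Any] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.se < 0:
            raise ValueError("standard error cannot be negative")
        if self.se == 0 and "degenerate" not in self.flags:
            raise ValueError("zero standard error must be flagged degenerate")

    @property
    def ok(self) -> bool:
        return len(self.flags) == 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "slope": self.slope,
            "se": self.se,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "n_used": self.n_used,
            "flags": ";".join(self.flags),
            **{f"extra_{k}": v for k, v in self.extras.items()},
        }


def _two_sided_p(statistic: float, df: float | None) -> float:
    if np.isnan(statistic):
        return np.nan
    if df is None:
        return 2.0 * stats.norm.sf(abs(statistic))
    return 2.0 * stats.t.sf(abs(statistic), df)


class NetworkRegressor(RegressorMixin, BaseEstimator):
    """Base class for the correction strategies.

    Subclasses implement ``_fit(x, y)`` on validated 1-D arrays and call
    ``_store`` with the slope, its SE and the reference distribution.
    """

    method: str = "base"

    def _validate_xy(self, X, y, min_n: int = 3):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("a single predictor trait is expected")
            x = x[:, 0]
        y = np.asarray(y, dtype=float).ravel()
        if x.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same length")
        if x.shape[0] < min_n:
            raise ValueError(f"need at least {min_n} observations")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")
        return x, y

    def _store(
        self,
        *,
        intercept: float,
        slope: float,
        se: float,
        df: float | None,
        n_used: int,
        extras: dict | None = None,
        flags: tuple[str, ...] = (),
        statistic: float | None = None,
    ) -> None:
        self.intercept_ = float(intercept)
        self.slope_ = float(slope)
        self.coef_ = np.array([self.slope_])
        self.se_ = float(se)
        if self.se_ == 0 and "degenerate" not in flags:
            # perfect fit: the statistic degenerates (p -> 0 for a nonzero slope)
            flags = flags + ("degenerate",)
        if statistic is None:
            if self.se_ > 0:
                statistic = self.slope_ / self.se_
            elif self.slope_ != 0:
                statistic = np.inf * np.sign(self.slope_)
            else:
                statistic = np.nan
        self.statistic_ = float(statistic)
        self.df_ = df
        self.p_value_ = float(_two_sided_p(self.statistic_, df))
        self.n_used_ = int(n_used)
        self.extras_ = dict(extras or {})
        self.flags_ = tuple(flags)

    def fit(self, X, y):
        x, yv = self._validate_xy(X, y)
        self._fit(x, yv)
        return self

    def _fit(self, x: np.ndarray, y: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.intercept_ + self.slope_ * x

    def fit_result(self) -> RegressionFit:
        return RegressionFit(
            method=self.method,
            slope=self.slope_,
            se=self.se_,
            statistic=self.statistic_,
            p_value=self.p_value_,
            df=self.df_,
            n_used=self.n_used_,
            extras=self.extras_,
            flags=self.flags_,
        )
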