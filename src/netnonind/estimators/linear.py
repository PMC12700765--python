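"""OLS-based strategies: naive regression, robust (HC1) standard errors,
spatial-HAC (Conley-style) standard errors on embedded coordinates, and
regression with embedding components as fixed covariates.

All four share the least-squares slope; they differ only in the variance
estimate (or in the covariate set) used to test it.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy.spatial.distance import squareform, pdist

from .base import DegenerateFitError, NetworkRegressor
from .embedding import EmbedCoords

__all__ = [
    "OrdinaryLeastSquares",
    "RobustStandardErrors",
    "ConleyStandardErrors",
    "NetworkComponentsRegression",
]


def _check_nonconstant(x: np.ndarray) -> None:
    if np.ptp(x) == 0:
        raise DegenerateFitError("predictor trait is constant")


class OrdinaryLeastSquares(NetworkRegressor):
    """Naive simple linear regression ``y = a + b x + e``, classical t test
    with ``n - 2`` degrees of freedom.  The uncorrected baseline."""

    method = "ols"

    def _fit(self, x, y):
        _check_nonconstant(x)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self._store(
            intercept=res.params[0],
            slope=res.params[1],
            se=res.bse[1],
            df=res.df_resid,
            n_used=x.shape[0],
            extras={"r_squared": float(res.rsquared)},
        )


class RobustStandardErrors(NetworkRegressor):
    """OLS slope tested with a heteroscedasticity-consistent sandwich SE.

    The HC1 variant rescales squared residuals by ``n / (n - k)``.  Robust
    SEs address non-identical error variances, not dependence between
    observations — including them probes how far that common practice goes.
    """

    method = "hc1"

    def __init__(self, cov_type: str = "HC1"):
        self.cov_type = cov_type

    def _fit(self, x, y):
        _check_nonconstant(x)
        res = sm.OLS(y, sm.add_constant(x)).fit(cov_type=self.cov_type, use_t=True)
        se = float(res.bse[1])
        # numerically-zero SE (perfect collinearity) is a degenerate fit
        degenerate = not np.isfinite(se) or se <= 1e-10 * (abs(res.params[1]) + 1.0)
        flags = ("degenerate",) if degenerate else ()
        self._store(
            intercept=res.params[0],
            slope=res.params[1],
            se=se,
            df=res.df_resid,
            n_used=x.shape[0],
            flags=flags,
            statistic=float(res.tvalues[1]) if se > 0 else np.nan,
        )


def _sandwich_kernel_se(Xd: np.ndarray, resid: np.ndarray, K: np.ndarray):
    """Slope SE from the generic sandwich (X'X)^-1 [U' K U] (X'X)^-1 with
    score rows U = X * resid and pair weights K."""
    U = Xd * resid[:, None]
    meat = U.T @ K @ U
    bread = np.linalg.inv(Xd.T @ Xd)
    cov = bread @ meat @ bread
    return cov[1, 1]


class ConleyStandardErrors(NetworkRegressor):
    """OLS slope with a spatial-HAC variance on embedded coordinates.

    The network is laid out in the plane by 2-component nonmetric MDS; the
    sandwich variance then sums score cross-products of observation pairs
    closer than ``cutoff`` in that plane (Bartlett taper by default,
    uniform optional).  Coordinates are treated as planar — no
    great-circle geometry.

    The default cutoff is the median nearest-neighbor embedded distance,
    so the kernel neighborhood stays local: HAC variance estimates are
    consistent only when the bandwidth is small relative to the sample
    extent, and generous cutoffs (a constant fraction of all pairs) make
    the estimate so noisy that the test over-rejects badly even on
    independent data.
    """

    method = "conley"

    def __init__(self, coords: EmbedCoords, cutoff: float | None = None, kernel: str = "bartlett"):
        self.coords = coords
        self.cutoff = cutoff
        self.kernel = kernel

    def _fit(self, x, y):
        _check_nonconstant(x)
        C = self.coords.coords
        if C.shape[0] != x.shape[0]:
            raise ValueError("coords rows must match the number of observations")
        if C.shape[1] != 2:
            raise ValueError("spatial-HAC correction expects a 2-D embedding")
        dist = squareform(pdist(C))
        cutoff = self.cutoff
        if cutoff is None:
            offdiag = dist + np.where(np.eye(len(dist), dtype=bool), np.inf, 0.0)
            cutoff = float(np.median(offdiag.min(axis=0)))
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.kernel == "uniform":
            K = (dist <= cutoff).astype(float)
        elif self.kernel == "bartlett":
            K = np.clip(1.0 - dist / cutoff, 0.0, None)
        else:
            raise ValueError(f"unknown kernel: {self.kernel}")
        np.fill_diagonal(K, 1.0)

        Xd = sm.add_constant(x)
        res = sm.OLS(y, Xd).fit()
        var = _sandwich_kernel_se(Xd, res.resid, K)
        flags = ()
        if var <= 0:
            # dependence correction can push the quadratic form negative
            flags = ("degenerate",)
            var = 0.0
        se = float(np.sqrt(var))
        self._store(
            intercept=res.params[0],
            slope=res.params[1],
            se=se,
            df=res.df_resid,
            n_used=x.shape[0],
            extras={"cutoff": cutoff, "kernel": self.kernel},
            flags=flags,
        )


class NetworkComponentsRegression(NetworkRegressor):
    """Regression with embedding components as fixed covariates.

    ``y = a + b x + c_1 C_1 + ... + c_k C_k + e``: the components encode each
    node's network position, so conditioning on them is meant to soak up the
    positional dependence.  Classical t test with ``n - k - 2`` df.
    """

    method = "pc5"

    def __init__(self, coords: EmbedCoords):
        self.coords = coords

    def _fit(self, x, y):
        _check_nonconstant(x)
        C = self.coords.coords
        if C.shape[0] != x.shape[0]:
            raise ValueError("coords rows must match the number of observations")
        n, k = C.shape
        if n <= k + 2:
            raise ValueError(f"need n > {k + 2} observations for {k} components")
        design = sm.add_constant(np.column_stack([x, C]))
        res = sm.OLS(y, design).fit()
        self._store(
            intercept=res.params[0],
            slope=res.params[1],
            se=res.bse[1],
            df=res.df_resid,
            n_used=n,
            extras={"n_components": k, "r_squared": float(res.rsquared)},
        )
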