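"""Network autocorrelation (spatial-error) regression.

The disturbance of each node is autocorrelated with its neighbors':

    y = X b + e,    e = rho * W * e + v,    v ~ N(0, sigma^2 I),

with ``W`` the raw binary adjacency matrix.  Writing S(rho) = I - rho W,
the log-likelihood is

    l = -(n/2) log(2 pi sigma^2) + log|S| - ||S (y - X b)||^2 / (2 sigma^2).

``rho`` is profile-optimized inside its spectral bounds
(1/lambda_min(W), 1/lambda_max(W)), where S stays invertible with positive
determinant; given rho, b and sigma^2 have closed forms.  Standard errors
come from the observed information (numerical Hessian at the optimum).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .base import NetworkRegressor

__all__ = ["NetworkAutocorrelationModel"]


def _negloglik(theta: np.ndarray, y, Xd, W, eigvals) -> float:
    b0, b1, rho, sigma2 = theta
    if sigma2 <= 0:
        return np.inf
    one_minus = 1.0 - rho * eigvals
    if np.any(one_minus <= 0):
        return np.inf
    n = y.shape[0]
    resid = y - Xd @ np.array([b0, b1])
    sr = resid - rho * (W @ resid)
    logdet = float(np.sum(np.log(one_minus)))
    return 0.5 * n * np.log(2 * np.pi * sigma2) - logdet + 0.5 * (sr @ sr) / sigma2


def _numeric_hessian(fun, theta: np.ndarray, steps: np.ndarray) -> np.ndarray:
    k = theta.size
    H = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            if i == j:
                H[i, i] = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(theta + ei + ej)
                    - fun(theta + ei - ej)
                    - fun(theta - ei + ej)
                    + fun(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


class NetworkAutocorrelationModel(NetworkRegressor):
    """Maximum-likelihood spatial-error regression on the adjacency matrix.

    Parameters
    ----------
    adjacency:
        ``(n, n)`` symmetric binary tie matrix.
    row_normalize:
        If True, rows of ``W`` are scaled to sum to one before fitting
        (sensitivity option; the default keeps the raw adjacency).
    """

    method = "lnam"

    #: relative margin kept inside the spectral bounds during optimization
    _bound_margin = 1e-6
    #: closeness to a bound (relative) that flags a boundary solution
    _bound_flag_tol = 1e-3

    def __init__(self, adjacency, row_normalize: bool = False):
        self.adjacency = adjacency
        self.row_normalize = row_normalize

    def _fit(self, x, y):
        W = np.asarray(self.adjacency, dtype=float)
        n = x.shape[0]
        if W.shape != (n, n):
            raise ValueError("adjacency shape must match the number of observations")
        if self.row_normalize:
            rowsum = W.sum(axis=1, keepdims=True)
            W = np.divide(W, rowsum, out=np.zeros_like(W), where=rowsum > 0)
            eigvals = np.linalg.eigvals(W).real
        else:
            eigvals = np.linalg.eigvalsh(W)
        lam_min, lam_max = float(eigvals.min()), float(eigvals.max())
        lo = 1.0 / lam_min if lam_min < 0 else -np.inf
        hi = 1.0 / lam_max if lam_max > 0 else np.inf
        span = hi - lo
        lo_in, hi_in = lo + self._bound_margin * span, hi - self._bound_margin * span

        Xd = np.column_stack([np.ones(n), x])

        def profile_negloglik(rho: float) -> float:
            S_y = y - rho * (W @ y)
            S_X = Xd - rho * (W @ Xd)
            beta, *_ = np.linalg.lstsq(S_X, S_y, rcond=None)
            resid = S_y - S_X @ beta
            sigma2 = (resid @ resid) / n
            if sigma2 <= 0:
                return np.inf
            logdet = float(np.sum(np.log(1.0 - rho * eigvals)))
            return 0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - logdet

        opt = minimize_scalar(
            profile_negloglik, bounds=(lo_in, hi_in), method="bounded",
            options={"xatol": 1e-6},
        )
        rho = float(opt.x)
        flags: list[str] = []
        if min(rho - lo, hi - rho) < self._bound_flag_tol * span:
            flags.append("rho_at_bound")

        S_y = y - rho * (W @ y)
        S_X = Xd - rho * (W @ Xd)
        beta, *_ = np.linalg.lstsq(S_X, S_y, rcond=None)
        resid = S_y - S_X @ beta
        sigma2 = float(resid @ resid) / n
        loglik = -float(opt.fun)

        theta = np.array([beta[0], beta[1], rho, sigma2])
        steps = np.maximum(1e-5, 1e-4 * np.abs(theta))
        steps[2] = min(steps[2], 0.25 * max(min(rho - lo, hi - rho), 1e-8))
        se = np.nan
        try:
            H = _numeric_hessian(
                lambda t: _negloglik(t, y, Xd, W, eigvals), theta, steps
            )
            cov = np.linalg.inv(H)
            var_slope = cov[1, 1]
            if var_slope > 0:
                se = float(np.sqrt(var_slope))
        except np.linalg.LinAlgError:
            pass
        if not np.isfinite(se):
            # fall back to the rho-conditional GLS variance
            flags.append("conditional_se")
            cov_beta = sigma2 * np.linalg.inv(S_X.T @ S_X)
            se = float(np.sqrt(cov_beta[1, 1]))

        self._store(
            intercept=beta[0],
            slope=beta[1],
            se=se,
            df=None,
            n_used=n,
            extras={
                "rho": rho,
                "sigma2": sigma2,
                "loglik": loglik,
                "rho_bounds": (lo, hi),
            },
            flags=tuple(flags),
        )
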