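"""Mixed-model strategies: community random effects and dyadic regression.

*Community random effects* detects communities (walktrap) and fits a
random-intercept linear mixed model grouped by community, so within-community
dependence is absorbed by the intercept variance.

*Dyadic regression* re-expresses the traits as pairwise distances: every
unordered node pair contributes one row with |y_i - y_j|, |x_i - x_j| and a
tie indicator Z, and the model

    y_dist = a + b x_dist + c Z + u_node_a + u_node_b + e

carries crossed random intercepts for the two member nodes (a single shared
variance).  Because every pair of nodes shares exactly one dyad, the
incidence structure has closed-form eigenvalues and the profile likelihood
over the variance ratio is evaluated in O(n^2) time via the Woodbury
identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from ..networks import CommunityPartition, Network
from .base import NetworkRegressor

__all__ = [
    "CommunityRandomEffects",
    "DyadTable",
    "build_dyads",
    "DyadicRegression",
    "dyadic_profile",
    "dyadic_negloglik",
]


class CommunityRandomEffects(NetworkRegressor):
    """Random-intercept mixed model grouped by network community (REML).

    The slope is tested with a Wald z statistic.  With a single community
    the variance component is unidentified and the estimator falls back to
    OLS with a warning.
    """

    method = "community_re"

    def __init__(self, partition: CommunityPartition):
        self.partition = partition

    def _ols_fallback(self, x, y, flag: str) -> None:
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self._store(
            intercept=res.params[0],
            slope=res.params[1],
            se=res.bse[1],
            df=res.df_resid,
            n_used=x.shape[0],
            flags=(flag,),
        )

    def _fit(self, x, y):
        labels = self.partition.labels
        if labels.shape[0] != x.shape[0]:
            raise ValueError("partition size must match the observations")
        if self.partition.n_communities < 2:
            warnings.warn(
                "single community: variance component unidentified, using OLS",
                stacklevel=2,
            )
            return self._ols_fallback(x, y, "single_community")
        exog = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, exog, groups=labels).fit(reml=True)
                fe = np.asarray(res.fe_params)
                bse_fe = np.asarray(res.bse_fe)
        except (np.linalg.LinAlgError, ValueError):
            return self._ols_fallback(x, y, "mixed_fit_failed")
        if not np.isfinite(bse_fe[1]) or bse_fe[1] <= 0:
            return self._ols_fallback(x, y, "mixed_fit_failed")
        self._store(
            intercept=float(fe[0]),
            slope=float(fe[1]),
            se=float(bse_fe[1]),
            df=None,  # Wald z
            n_used=x.shape[0],
            extras={
                "community_var": float(np.asarray(res.cov_re)[0, 0]),
                "residual_var": float(res.scale),
                "n_communities": self.partition.n_communities,
            },
        )


@dataclass(frozen=True)
class DyadTable:
    """All unordered node pairs with trait distances and a tie indicator."""

    node_a: np.ndarray
    node_b: np.ndarray
    y_dist: np.ndarray
    x_dist: np.ndarray
    z: np.ndarray
    n_nodes: int

    def __post_init__(self):
        m = self.n_nodes * (self.n_nodes - 1) // 2
        if not (
            len(self.node_a) == len(self.node_b) == len(self.y_dist)
            == len(self.x_dist) == len(self.z) == m
        ):
            raise ValueError(f"a dyad table over {self.n_nodes} nodes needs {m} rows")

    @property
    def n_dyads(self) -> int:
        return len(self.y_dist)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node_a": self.node_a,
                "node_b": self.node_b,
                "y_dist": self.y_dist,
                "x_dist": self.x_dist,
                "z": self.z,
            }
        )


def build_dyads(y, x, net: Network, distance: str = "abs") -> DyadTable:
    """One row per unordered pair: trait distances and the tie indicator."""
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    n = net.n_nodes
    if y.shape[0] != n or x.shape[0] != n:
        raise ValueError("trait vectors must match the number of nodes")
    ia, ib = np.triu_indices(n, k=1)
    dy = np.abs(y[ia] - y[ib])
    dx = np.abs(x[ia] - x[ib])
    if distance == "squared":
        dy, dx = dy**2, dx**2
    elif distance != "abs":
        raise ValueError(f"unknown distance: {distance}")
    z = net.adjacency[ia, ib].astype(float)
    return DyadTable(node_a=ia, node_b=ib, y_dist=dy, x_dist=dx, z=z, n_nodes=n)


def _dyad_vinv(dt: DyadTable, M: np.ndarray, gamma: float) -> np.ndarray:
    """(I + gamma A A')^-1 M via the Woodbury identity.

    ``A`` is the (n_dyads, n_nodes) membership incidence; every node pair
    shares exactly one dyad, so A'A = (n-2) I + J and the inner inverse is
    closed-form.
    """
    if gamma == 0:
        return M
    n = dt.n_nodes
    ia, ib = dt.node_a, dt.node_b
    M2 = np.atleast_2d(M.T).T
    AtM = np.column_stack(
        [
            np.bincount(ia, weights=M2[:, j], minlength=n)
            + np.bincount(ib, weights=M2[:, j], minlength=n)
            for j in range(M2.shape[1])
        ]
    )
    a = 1.0 / gamma + (n - 2.0)
    Ginv_AtM = (AtM - AtM.sum(axis=0, keepdims=True) / (a + n)) / a
    out = M2 - (Ginv_AtM[ia] + Ginv_AtM[ib])
    return out[:, 0] if M.ndim == 1 else out


def _dyad_logdet(dt: DyadTable, gamma: float) -> float:
    # eigenvalues of A'A are 2n-2 (once) and n-2 (n-1 times)
    n = dt.n_nodes
    return float(np.log1p(gamma * (2 * n - 2)) + (n - 1) * np.log1p(gamma * (n - 2)))


def dyadic_profile(dt: DyadTable, gamma: float):
    """GLS pieces of the dyadic mixed model at variance ratio ``gamma``.

    Returns ``(beta, FtViF, q, logdet)`` where ``q`` is the GLS residual
    quadratic form; used both by the fitter and as an externally checkable
    surface.
    """
    m = dt.n_dyads
    F = np.column_stack([np.ones(m), dt.x_dist, dt.z])
    ViF = _dyad_vinv(dt, F, gamma)
    Viy = _dyad_vinv(dt, dt.y_dist, gamma)
    FtViF = F.T @ ViF
    beta = np.linalg.solve(FtViF, F.T @ Viy)
    resid = dt.y_dist - F @ beta
    q = float(resid @ _dyad_vinv(dt, resid, gamma))
    return beta, FtViF, q, _dyad_logdet(dt, gamma)


def dyadic_negloglik(dt: DyadTable, gamma: float) -> float:
    """Profile negative log-likelihood of the dyadic mixed model."""
    _, _, q, logdet = dyadic_profile(dt, gamma)
    if q <= 0:
        return np.inf
    m = dt.n_dyads
    return 0.5 * (m * np.log(2 * np.pi * q / m) + logdet + m)


class DyadicRegression(NetworkRegressor):
    """ML mixed model on the dyad table with crossed node random intercepts.

    ``fit(X, y)`` takes the node-level traits and builds the dyad table from
    the constructor's network; :meth:`fit_dyads` accepts a prebuilt table.
    The reported slope is the coefficient on the pairwise predictor
    distance, tested by Wald z.
    """

    method = "dyadic"

    _gamma_upper = 1e3  # search bound for the node-to-residual variance ratio

    def __init__(self, network: Network | None = None, distance: str = "abs"):
        self.network = network
        self.distance = distance

    def _fit(self, x, y):
        if self.network is None:
            raise ValueError("DyadicRegression needs a network to build dyads")
        self.fit_dyads(build_dyads(y, x, self.network, distance=self.distance))

    def fit_dyads(self, dt: DyadTable):
        n = dt.n_nodes
        m = dt.n_dyads
        yv = dt.y_dist

        def profile(gamma: float):
            beta, FtViF, q, _ = dyadic_profile(dt, gamma)
            return beta, FtViF, q

        def negloglik(gamma: float) -> float:
            return dyadic_negloglik(dt, gamma)

        flags: list[str] = []
        if np.ptp(yv) == 0:
            # constant outcome distances: slope 0 by construction
            self._store(
                intercept=float(yv.mean()), slope=0.0, se=0.0, statistic=np.nan,
                df=None, n_used=n, flags=("degenerate",),
            )
            return self

        try:
            opt = minimize_scalar(
                negloglik, bounds=(0.0, self._gamma_upper), method="bounded",
                options={"xatol": 1e-8},
            )
            gamma = float(opt.x)
            if negloglik(0.0) <= opt.fun:
                gamma = 0.0  # no node variance: plain OLS on dyads
            converged = bool(opt.success)
        except (np.linalg.LinAlgError, ValueError):
            gamma, converged = 0.0, False
        if not converged:
            flags.append("nonconverged")

        beta, FtViF, q = profile(gamma)
        sigma2_e = q / m
        cov_beta = sigma2_e * np.linalg.inv(FtViF)
        var_slope = cov_beta[1, 1]
        if var_slope <= 0:
            flags.append("degenerate")
        se = float(np.sqrt(max(var_slope, 0.0)))
        self._store(
            intercept=beta[0],
            slope=beta[1],
            se=se,
            df=None,
            n_used=n,
            extras={
                "tie_coef": float(beta[2]),
                "gamma": gamma,
                "sigma2_e": sigma2_e,
                "sigma2_node": gamma * sigma2_e,
                "loglik": -negloglik(gamma) if np.isfinite(negloglik(gamma)) else np.nan,
                "n_dyads": m,
            },
            flags=tuple(flags),
        )
        return self
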