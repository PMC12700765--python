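"""Tree-based (phylogenetic-style) autoregression.

The network is first simplified to its closest-fitting ultrametric tree by
agglomerative (complete-linkage) clustering of a node dissimilarity.  The
default dissimilarity in the simulation harness is the Euclidean distance
between adjacency-matrix rows — the result of handing the tie matrix
straight to a distance-then-cluster pipeline, so two nodes are close when
their tie *profiles* agree; clustering geodesic distances is the
alternative (see :func:`adjacency_row_distances`).  Shared depth in the
dendrogram plays the role of shared branch length on a phylogeny: the
baseline correlation between nodes i and j is

    C0_ij = 1 - h_ij / h_max,

where ``h_ij`` is the merge (cophenetic) height and ``h_max`` the tree
depth.  Pagel's lambda then scales the off-diagonal correlations,
C(lambda) = (1 - lambda) I + lambda C0, and the regression is fitted by GLS
with lambda chosen by profile maximum likelihood on [0, 1].  lambda = 0
recovers ordinary least squares exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from ..networks import finite_distances
from .base import NetworkRegressor

__all__ = [
    "TreeCorrelation",
    "adjacency_row_distances",
    "build_tree",
    "PhylogeneticGLS",
]


def adjacency_row_distances(adjacency: np.ndarray) -> np.ndarray:
    """Euclidean distances between adjacency-matrix rows (tie profiles)."""
    from scipy.spatial.distance import pdist, squareform as to_square

    return to_square(pdist(np.asarray(adjacency, dtype=float)))


@dataclass(frozen=True)
class TreeCorrelation:
    """Ultrametric dendrogram summary: linkage matrix, cophenetic heights,
    and the baseline (lambda = 1) correlation matrix."""

    linkage_matrix: np.ndarray
    cophenetic: np.ndarray  # (n, n) merge heights, zero diagonal
    corr: np.ndarray  # (n, n) baseline correlation, unit diagonal

    @property
    def n_leaves(self) -> int:
        return self.corr.shape[0]


def build_tree(D: np.ndarray, method: str = "complete") -> TreeCorrelation:
    """Agglomerative clustering of a geodesic distance matrix into an
    ultrametric tree; infinite entries are replaced by diameter + 1."""
    Df = finite_distances(D)
    Z = linkage(squareform(Df, checks=False), method=method)
    heights = squareform(cophenet(Z))
    h_max = heights.max()
    if h_max <= 0:
        corr = np.ones_like(heights)
    else:
        corr = 1.0 - heights / h_max
    np.fill_diagonal(corr, 1.0)
    return TreeCorrelation(linkage_matrix=Z, cophenetic=heights, corr=corr)


class PhylogeneticGLS(NetworkRegressor):
    """GLS regression with a Pagel-lambda tree correlation structure.

    Parameters
    ----------
    tree:
        Output of :func:`build_tree`.
    lam:
        If given, lambda is held fixed instead of estimated by profile ML.
    """

    method = "pagel_gls"

    def __init__(self, tree: TreeCorrelation, lam: float | None = None):
        self.tree = tree
        self.lam = lam

    def _fit(self, x, y):
        C0 = self.tree.corr
        n = x.shape[0]
        if C0.shape != (n, n):
            raise ValueError("tree correlation shape must match the observations")
        Xd = np.column_stack([np.ones(n), x])
        eye = np.eye(n)

        def gls_pieces(lam: float):
            C = (1.0 - lam) * eye + lam * C0
            try:
                cf = cho_factor(C, lower=True)
            except np.linalg.LinAlgError:
                return None
            Ci_X = cho_solve(cf, Xd)
            Ci_y = cho_solve(cf, y)
            XtCiX = Xd.T @ Ci_X
            beta = np.linalg.solve(XtCiX, Xd.T @ Ci_y)
            resid = y - Xd @ beta
            q = float(resid @ cho_solve(cf, resid))
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return beta, XtCiX, q, logdet

        def negloglik(lam: float) -> float:
            pieces = gls_pieces(lam)
            if pieces is None or pieces[2] <= 0:
                return np.inf  # non-PD candidate: penalized out
            _, _, q, logdet = pieces
            sigma2 = q / n
            return 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

        flags: list[str] = []
        if self.lam is not None:
            lam_hat = float(self.lam)
            if not 0.0 <= lam_hat <= 1.0:
                raise ValueError("lambda must lie in [0, 1]")
        else:
            opt = minimize_scalar(
                negloglik, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
            )
            lam_hat = float(opt.x)
            # a bounded search never lands exactly on an interior-optimal edge;
            # snap to the edge when it is (numerically) at least as good
            for edge in (0.0, 1.0):
                if negloglik(edge) <= negloglik(lam_hat):
                    lam_hat = edge

        pieces = gls_pieces(lam_hat)
        if pieces is None:
            raise np.linalg.LinAlgError("correlation matrix not positive definite")
        beta, XtCiX, q, _ = pieces
        sigma2 = q / (n - 2)  # unbiased residual variance for the t test
        cov_beta = sigma2 * np.linalg.inv(XtCiX)
        var_slope = cov_beta[1, 1]
        if var_slope <= 0:
            flags.append("degenerate")
        se = float(np.sqrt(max(var_slope, 0.0)))
        self._store(
            intercept=beta[0],
            slope=beta[1],
            se=se,
            df=n - 2,
            n_used=n,
            extras={"lambda": lam_hat, "loglik": -negloglik(lam_hat)},
            flags=tuple(flags),
        )
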