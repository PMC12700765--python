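"""Regression strategies for trait association on networks.

Estimator classes follow the scikit-learn protocol; the ``fit_*`` functions
are thin wrappers that return the uniform :class:`RegressionFit` record.
"""

from __future__ import annotations

import numpy as np

from ..networks import CommunityPartition
from .autoregression import NetworkAutocorrelationModel
from .base import DegenerateFitError, NetworkRegressor, RegressionFit
from .embedding import EmbedCoords, classical_mds, embed_network, kruskal_stress
from .linear import (
    ConleyStandardErrors,
    NetworkComponentsRegression,
    OrdinaryLeastSquares,
    RobustStandardErrors,
)
from .mixed import CommunityRandomEffects, DyadicRegression, DyadTable, build_dyads
from .subsample import NodeSubsampleOLS
from .tree import (
    PhylogeneticGLS,
    TreeCorrelation,
    adjacency_row_distances,
    build_tree,
)

__all__ = [
    "RegressionFit",
    "DegenerateFitError",
    "NetworkRegressor",
    "OrdinaryLeastSquares",
    "RobustStandardErrors",
    "ConleyStandardErrors",
    "NetworkComponentsRegression",
    "CommunityRandomEffects",
    "NetworkAutocorrelationModel",
    "PhylogeneticGLS",
    "DyadicRegression",
    "NodeSubsampleOLS",
    "EmbedCoords",
    "TreeCorrelation",
    "DyadTable",
    "classical_mds",
    "embed_network",
    "kruskal_stress",
    "adjacency_row_distances",
    "build_tree",
    "build_dyads",
    "fit_ols",
    "fit_robust_hc1",
    "fit_conley",
    "fit_pc_covariates",
    "fit_community_re",
    "fit_lnam",
    "fit_pagel_gls",
    "fit_dyadic",
    "fit_subsample",
]


def fit_ols(y, X) -> RegressionFit:
    """Naive simple linear regression of ``y`` on ``X``."""
    return OrdinaryLeastSquares().fit(X, y).fit_result()


def fit_robust_hc1(y, X) -> RegressionFit:
    """OLS slope with an HC1 heteroscedasticity-robust standard error."""
    return RobustStandardErrors().fit(X, y).fit_result()


def fit_conley(y, X, coords: EmbedCoords, cutoff: float | None = None,
               kernel: str = "bartlett") -> RegressionFit:
    """OLS slope with spatial-HAC standard errors on embedded coordinates."""
    return ConleyStandardErrors(coords, cutoff=cutoff, kernel=kernel).fit(X, y).fit_result()


def fit_pc_covariates(y, X, coords: EmbedCoords) -> RegressionFit:
    """Regression with the embedding components as fixed covariates."""
    return NetworkComponentsRegression(coords).fit(X, y).fit_result()


def fit_community_re(y, X, part: CommunityPartition) -> RegressionFit:
    """Random-intercept mixed model grouped by network community."""
    return CommunityRandomEffects(part).fit(X, y).fit_result()


def fit_lnam(y, X, W) -> RegressionFit:
    """Maximum-likelihood network autocorrelation (spatial-error) model."""
    return NetworkAutocorrelationModel(np.asarray(W)).fit(X, y).fit_result()


def fit_pagel_gls(y, X, tc: TreeCorrelation) -> RegressionFit:
    """GLS with a Pagel-lambda correlation structure on a network tree."""
    return PhylogeneticGLS(tc).fit(X, y).fit_result()


def fit_dyadic(dt: DyadTable) -> RegressionFit:
    """Dyadic mixed model with crossed node random intercepts."""
    return DyadicRegression().fit_dyads(dt).fit_result()


def fit_subsample(y, X, fraction: float, seed=None) -> RegressionFit:
    """OLS on a simple random sample of nodes."""
    return NodeSubsampleOLS(fraction, seed=seed).fit(X, y).fit_result()
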