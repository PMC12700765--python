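"""Random node subsampling.

Drawing a small simple random sample of nodes makes sampled pairs unlikely
to be directly tied, so the subsample behaves approximately like
independent observations — at an obvious cost in power.  The estimator
draws ``round(fraction * n)`` nodes without replacement and runs plain OLS
on the subsample.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .base import NetworkRegressor
from .linear import _check_nonconstant

__all__ = ["NodeSubsampleOLS"]


class NodeSubsampleOLS(NetworkRegressor):
    """OLS on a simple random sample of ``round(fraction * n)`` nodes.

    Subsample size rounds half-up.  With ``fraction=1`` the estimator is
    identical to :class:`OrdinaryLeastSquares` (indices are kept sorted, so
    the arithmetic matches bit for bit).
    """

    def __init__(self, fraction: float, seed=None):
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        self.fraction = fraction
        self.seed = seed

    @property
    def method(self) -> str:  # type: ignore[override]
        return f"subsample_{int(round(self.fraction * 100))}"

    def _fit(self, x, y):
        n = x.shape[0]
        size = int(np.floor(self.fraction * n + 0.5))
        if size < 3:
            raise ValueError(
                f"subsample of {size} nodes (fraction={self.fraction}) is too small"
            )
        if size >= n:
            idx = np.arange(n)
        else:
            rng = self.seed if isinstance(self.seed, np.random.Generator) else np.random.default_rng(self.seed)
            idx = np.sort(rng.choice(n, size=size, replace=False))
        self.sampled_nodes_ = idx
        xs, ys = x[idx], y[idx]
        _check_nonconstant(xs)
        res = sm.OLS(ys, sm.add_constant(xs)).fit()
        self._store(
            intercept=res.params[0],
            slope=res.params[1],
            se=res.bse[1],
            df=res.df_resid,
            n_used=size,
            extras={"fraction": self.fraction},
        )
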