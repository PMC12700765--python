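"""Low-dimensional embedding of the network for spatial-style corrections.

Geodesic distances are embedded by Kruskal nonmetric MDS — preserving the
rank order of pairwise network distances — initialized from classical
(Torgerson) metric MDS.  Two components stand in for "latitude/longitude"
in the spatial-HAC correction; five components serve as fixed covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.manifold import MDS

from ..networks import finite_distances

__all__ = ["EmbedCoords", "classical_mds", "embed_network", "kruskal_stress"]


@dataclass(frozen=True)
class EmbedCoords:
    """``(n, k)`` embedded coordinates plus the final Kruskal stress-1."""

    coords: np.ndarray
    stress: float

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric MDS: eigendecomposition of the double-centered
    squared-distance matrix, keeping the top ``k`` positive components."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def kruskal_stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 of ``coords`` against the monotone (isotonic) regression of
    embedded distances on the rank order of ``D`` (average ranks for ties)."""
    from sklearn.isotonic import IsotonicRegression

    delta = D[np.triu_indices_from(D, k=1)]
    d = pdist(coords)
    ranks = rankdata(delta, method="average")
    dhat = IsotonicRegression().fit_transform(ranks, d)
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def embed_network(
    D: np.ndarray,
    k: int,
    seed=0,
    max_iter: int = 150,
    eps: float = 1e-5,
) -> EmbedCoords:
    """Nonmetric MDS of a geodesic distance matrix into ``k`` dimensions.

    Infinite entries (disconnected pairs) are replaced by diameter + 1
    before embedding.  The SMACOF refinement starts from the classical MDS
    solution; ``seed`` only matters for degenerate tie-breaking inside the
    solver, so the embedding is reproducible.
    """
    D = finite_distances(D)
    n = D.shape[0]
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < n")
    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=1,
        init="classical_mds",
        max_iter=max_iter,
        eps=eps,
        random_state=None if seed is None else int(seed),
        normalized_stress=True,
    )
    coords = mds.fit_transform(D)
    return EmbedCoords(coords=coords, stress=float(mds.stress_))
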