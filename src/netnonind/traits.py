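"""Node traits and the social-influence diffusion process.

Traits are continuous node attributes (e.g. a prescribing rate).  The study
conditions are deliberately simple: each trait starts as an i.i.d. standard
normal draw per node, then a single influence step moves every node
part-way toward the mean of its direct neighbors,

    x_i <- x_i + s * (mean_{j in N(i)} x_j - x_i),     s = 0.5 by default.

The default update sweeps nodes in index order *in place*, so later nodes
see their earlier neighbors' already-updated values — the behavior of a
straightforward scripted loop over nodes.  A strictly synchronous variant
(all neighbor means computed from pre-step values) is available via
``DiffusionConfig(update_mode="synchronous")``.

Traits diffuse independently of one another, so any association detected
between two diffused traits is a false positive — the nonindependence the
corrections are supposed to absorb lives entirely in the error structure.

For power studies a trait pair is constructed with an *exact* realized
Pearson correlation (orthogonalize-and-rotate), then both columns diffuse
by the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .networks import Network

__all__ = [
    "TraitMatrix",
    "DiffusionConfig",
    "initial_traits",
    "diffuse",
    "correlated_pair",
    "make_null_dataset",
    "make_power_dataset",
]


@dataclass
class TraitMatrix:
    """``(n_nodes, n_traits)`` real matrix plus generation metadata."""

    values: np.ndarray
    seed: int | None = None
    diffused: bool = False
    target_r: float | None = None

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.ndim != 2:
            raise ValueError("trait values must be a 2-D array")
        if values.shape[1] < 1:
            raise ValueError("need at least one trait column")
        if not np.isfinite(values).all():
            raise ValueError("trait values must be finite")
        self.values = values

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def column(self, k: int) -> np.ndarray:
        return self.values[:, k]

    def to_csv(self, path, node_ids=None) -> None:
        width = max(4, len(str(self.n_traits)))
        cols = [f"trait_{k + 1:0{width}d}" for k in range(self.n_traits)]
        frame = pd.DataFrame(self.values, columns=cols)
        frame.insert(0, "node_id", node_ids if node_ids is not None else np.arange(self.n_nodes))
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TraitMatrix":
        frame = pd.read_csv(path)
        if "node_id" in frame.columns:
            frame = frame.drop(columns=["node_id"])
        return cls(values=frame.to_numpy(dtype=float))


@dataclass(frozen=True)
class DiffusionConfig:
    """Parameters of the influence update.

    ``step_fraction`` is the share of the gap to the neighborhood mean closed
    in one step (0 = no influence, 1 = full adoption of the local mean).
    ``update_mode`` is ``"sequential"`` (in-place sweep in node-index order,
    the default) or ``"synchronous"`` (all updates from pre-step values).
    """

    step_fraction: float = 0.5
    n_steps: int = 1
    update_mode: str = "sequential"

    def __post_init__(self):
        if not 0.0 <= self.step_fraction <= 1.0:
            raise ValueError("step_fraction must lie in [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.update_mode not in {"sequential", "synchronous"}:
            raise ValueError("update_mode must be 'sequential' or 'synchronous'")


def initial_traits(n_nodes: int, n_traits: int, seed=None) -> TraitMatrix:
    """Draw i.i.d. standard-normal starting values, one column per trait."""
    if n_nodes < 1 or n_traits < 1:
        raise ValueError("n_nodes and n_traits must be positive")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_nodes, n_traits))
    return TraitMatrix(values=values, seed=seed if isinstance(seed, int) else None)


def diffuse(traits: TraitMatrix, net: Network, cfg: DiffusionConfig | None = None) -> TraitMatrix:
    """Apply the influence update ``cfg.n_steps`` times.

    In the default sequential mode nodes are visited in index order and each
    update uses the neighbors' *current* values (earlier nodes in the sweep
    have already moved).  In synchronous mode every neighbor mean is computed
    from pre-step values.  Isolated nodes (degree 0) are left unchanged.
    """
    cfg = cfg or DiffusionConfig()
    if traits.n_nodes != net.n_nodes:
        raise ValueError(
            f"trait matrix has {traits.n_nodes} rows but network has {net.n_nodes} nodes"
        )
    A = net.adjacency.astype(bool)
    deg = net.degrees.astype(float)
    connected = deg > 0
    s = cfg.step_fraction
    values = traits.values.copy()
    if cfg.update_mode == "synchronous":
        Af = A.astype(float)
        for _ in range(cfg.n_steps):
            neighbor_mean = np.where(
                connected[:, None],
                (Af @ values) / np.where(connected, deg, 1.0)[:, None],
                values,
            )
            values = values + s * (neighbor_mean - values)
    else:
        neighbor_lists = [np.flatnonzero(A[i]) for i in range(net.n_nodes)]
        for _ in range(cfg.n_steps):
            for i, nb in enumerate(neighbor_lists):
                if nb.size:
                    values[i] += s * (values[nb].mean(axis=0) - values[i])
    return replace(traits, values=values, diffused=True)


def correlated_pair(n_nodes: int, r: float, seed=None) -> TraitMatrix:
    """Two trait columns with sample Pearson correlation exactly ``r``.

    Draws two independent normal columns, replaces the second by the
    appropriately scaled combination of the standardized first column and
    the standardized residual of the second, so the realized (not merely
    expected) correlation hits the target.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes for a correlated pair")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_nodes, 2))
    a = z[:, 0] - z[:, 0].mean()
    b = z[:, 1] - z[:, 1].mean()
    resid = b - (b @ a) / (a @ a) * a
    a_unit = a / np.linalg.norm(a)
    resid_unit = resid / np.linalg.norm(resid)
    scale = np.sqrt(n_nodes - 1.0)  # restore sd ~ 1 marginals
    x1 = z[:, 0]
    x2 = scale * (r * a_unit + np.sqrt(1.0 - r * r) * resid_unit)
    values = np.column_stack([x1, x2])
    return TraitMatrix(
        values=values, seed=seed if isinstance(seed, int) else None, target_r=float(r)
    )


def make_null_dataset(
    net: Network,
    n_traits: int = 1000,
    seed=None,
    cfg: DiffusionConfig | None = None,
) -> TraitMatrix:
    """Independently generated traits, each diffused on ``net``.

    The null condition of the study: traits share no relationship beyond
    having diffused across the same ties.
    """
    traits = initial_traits(net.n_nodes, n_traits, seed=seed)
    return diffuse(traits, net, cfg)


def make_power_dataset(
    net: Network,
    r: float,
    seed=None,
    cfg: DiffusionConfig | None = None,
    diffuse_traits: bool = True,
) -> TraitMatrix:
    """A correlated trait pair for power studies, diffused by default."""
    traits = correlated_pair(net.n_nodes, r, seed=seed)
    if diffuse_traits:
        traits = diffuse(traits, net, cfg)
    return traits
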