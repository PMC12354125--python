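"""Seeded simulation of sample paths and randomized model generators.

Sampling uses inverse-CDF draws over precomputed row CDFs so that identical
seeds give bit-identical paths on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    BMCModel,
    ClusterAssignment,
    HigherOrderClusterModel,
    state_equilibrium,
    state_transition_matrix,
)
from .paths import SamplePath

__all__ = [
    "SimulationConfig",
    "sample_path",
    "sample_model_path",
    "sample_path_higher_order",
    "random_bmc",
    "random_stochastic_matrix",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Length, seed, and initial law of a simulation run.

    ``initial`` is ``"equilibrium"`` (default), ``"uniform"``, a fixed state
    index, or — for order-``r`` models — a tuple of ``r`` initial states.
    """

    length: int
    seed: int = 0
    initial: object = "equilibrium"

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")


def _inverse_cdf(cdf_row: np.ndarray, u: float) -> int:
    return int(np.searchsorted(cdf_row, u, side="right"))


def _draw_initial(P: np.ndarray, config: SimulationConfig, rng) -> int:
    n = P.shape[0]
    if config.initial == "equilibrium":
        from .models import _check_ergodic, _validate_rows

        p = _validate_rows(P, "P")
        _check_ergodic(p, warn_periodic=False)
        # stationary law of the full kernel
        a = p.T - np.eye(n)
        a[-1, :] = 1.0
        b = np.zeros(n)
        b[-1] = 1.0
        pi = np.clip(np.linalg.solve(a, b), 0.0, None)
        pi /= pi.sum()
        cdf = np.cumsum(pi)
        cdf[-1] = 1.0
        return min(_inverse_cdf(cdf, rng.random()), n - 1)
    if config.initial == "uniform":
        return int(rng.integers(n))
    return int(config.initial)


def sample_path(P, config: SimulationConfig) -> SamplePath:
    """Simulate a path from an ``n x n`` stochastic kernel ``P``."""
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if P.ndim != 2 or P.shape[1] != n:
        raise ValueError("P must be square")
    rows = P.sum(axis=1)
    if np.any(P < 0) or np.any(np.abs(rows - 1.0) > 1e-9):
        raise ValueError("P must be row-stochastic")
    rng = np.random.default_rng(config.seed)
    x = _draw_initial(P, config, rng)
    ell = config.length
    cdf = np.cumsum(P, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(ell - 1)
    out = np.empty(ell, dtype=np.int64)
    out[0] = x
    for t in range(ell - 1):
        x = min(_inverse_cdf(cdf[x], u[t]), n - 1)
        out[t + 1] = x
    return SamplePath(out, n=n)


def sample_model_path(model: BMCModel, config: SimulationConfig) -> SamplePath:
    """Simulate a BMC by its cluster chain, then uniform choice in-cluster.

    Distributionally identical to :func:`sample_path` on the full kernel but
    O(K) per step instead of O(log n).
    """
    assignment = model.assignment
    K, n = assignment.K, assignment.n
    sizes = assignment.sizes
    members = [assignment.members(k) for k in range(K)]
    rng = np.random.default_rng(config.seed)
    if config.initial == "equilibrium":
        from .models import cluster_equilibrium

        pi = cluster_equilibrium(model.p)
        cdf0 = np.cumsum(pi)
        cdf0[-1] = 1.0
        k = min(_inverse_cdf(cdf0, rng.random()), K - 1)
        x = int(members[k][rng.integers(sizes[k])])
    elif config.initial == "uniform":
        x = int(rng.integers(n))
    else:
        x = int(config.initial)
    ell = config.length
    cdf = np.cumsum(model.p, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random((ell - 1, 2))
    labels = assignment.labels
    out = np.empty(ell, dtype=np.int64)
    out[0] = x
    for t in range(ell - 1):
        k = min(_inverse_cdf(cdf[labels[x]], u[t, 0]), K - 1)
        x = int(members[k][min(int(u[t, 1] * sizes[k]), sizes[k] - 1)])
        out[t + 1] = x
    return SamplePath(out, n=n)


def sample_path_higher_order(
    model: HigherOrderClusterModel, config: SimulationConfig
) -> SamplePath:
    """Simulate an ``r``-th order clustered Markov chain.

    The next cluster depends on the clusters of the last ``r`` states; the
    state within the chosen cluster is uniform.  The first ``r`` states are
    taken from ``config.initial`` when it is a tuple, else drawn uniformly.
    """
    r = model.order
    assignment = model.assignment
    K, n = assignment.K, assignment.n
    if config.length <= r:
        raise ValueError(f"length must exceed the order r={r}")
    sizes = assignment.sizes
    members = [assignment.members(k) for k in range(K)]
    labels = assignment.labels
    rng = np.random.default_rng(config.seed)
    out = np.empty(config.length, dtype=np.int64)
    if isinstance(config.initial, (tuple, list)) and r > 0:
        if len(config.initial) != r:
            raise ValueError(f"initial must supply exactly r={r} states")
        out[:r] = np.asarray(config.initial, dtype=np.int64)
    else:
        out[:r] = rng.integers(n, size=r)
    cdf = np.cumsum(model.q, axis=1)
    cdf[:, -1] = 1.0
    steps = config.length - r
    u = rng.random((steps, 2))
    ctx = 0
    for i in range(r):
        ctx = ctx * K + int(labels[out[i]])
    mod = K ** max(r - 1, 0)
    for t in range(steps):
        k = min(_inverse_cdf(cdf[ctx], u[t, 0]), K - 1)
        x = int(members[k][min(int(u[t, 1] * sizes[k]), sizes[k] - 1)])
        out[r + t] = x
        if r > 0:
            ctx = (ctx % mod) * K + k
    return SamplePath(out, n=n)


def random_stochastic_matrix(
    n: int, mode: str = "dirichlet", seed: int = 0, density: float = 0.3
) -> np.ndarray:
    """Random row-stochastic matrices used as perturbation kernels.

    ``uniform-rows`` returns the matrix with all entries ``1/n``;
    ``dirichlet`` draws each row from a flat Dirichlet; ``sparse`` puts
    Dirichlet weights on about ``density * n`` uniformly chosen support
    entries per row.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "uniform-rows":
        return np.full((n, n), 1.0 / n)
    if mode == "dirichlet":
        return rng.dirichlet(np.ones(n), size=n)
    if mode == "sparse":
        out = np.zeros((n, n))
        nnz = max(1, int(round(density * n)))
        for i in range(n):
            support = rng.choice(n, size=nnz, replace=False)
            out[i, support] = rng.dirichlet(np.ones(nnz))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def random_bmc(n: int, K: int, separation: float, seed: int = 0) -> BMCModel:
    """A random planted BMC for synthetic experiments.

    Cluster sizes are balanced-as-possible (contiguous blocks).  The cluster
    matrix is ``p = (1 - separation)/K + separation * D`` with ``D`` drawn
    row-wise from a flat Dirichlet and redrawn until its rows are pairwise
    distinct (total-variation distance >= 0.05), so that ``separation -> 0``
    approaches the uninformative uniform chain and ``separation = 1`` gives
    well-separated clusters.
    """
    if not 0.0 < separation <= 1.0:
        raise ValueError("separation must lie in (0, 1]")
    if K > n:
        raise ValueError("need K <= n")
    rng = np.random.default_rng(seed)
    for _ in range(200):
        D = rng.dirichlet(np.ones(K), size=K)
        dists = [
            0.5 * np.abs(D[a] - D[b]).sum()
            for a in range(K)
            for b in range(a + 1, K)
        ]
        if K == 1 or min(dists) >= 0.05:
            break
    else:  # pragma: no cover - Dirichlet rows collide with probability ~0
        raise RuntimeError("could not draw a row-distinct cluster matrix")
    p = (1.0 - separation) / K + separation * D
    return BMCModel(ClusterAssignment.balanced(n, K), p)
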