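"""The block Markov chain model family.

A *block Markov chain* (BMC) on ``n`` states is a Markov chain whose state
space is partitioned into ``K`` clusters ``V_1, ..., V_K`` such that the
transition probability between two states depends only on their clusters,
with the destination state chosen uniformly inside the destination cluster:

.. math::

    P_{ij} = \\frac{p_{\\sigma(i), \\sigma(j)}}{\\#V_{\\sigma(j)}},

where ``sigma`` is the cluster assignment map and ``p`` is a row-stochastic
``K x K`` cluster transition matrix.  The module also provides the 0th-order
special case (i.i.d. sampling with cluster-constant law), clustered Markov
chains of arbitrary order ``r``, and convex perturbations of a BMC kernel by
an arbitrary stochastic matrix.

Indices are 0-based internally; human-readable output is 1-based.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ClusterAssignment",
    "BMCModel",
    "HigherOrderClusterModel",
    "make_bmc",
    "make_zeroth_order",
    "make_higher_order",
    "state_transition_matrix",
    "cluster_equilibrium",
    "state_equilibrium",
    "perturb",
    "write_model",
    "read_model",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ClusterAssignment:
    """A map from the ``n`` states to ``K`` clusters.

    ``labels[i]`` is the 0-based cluster of state ``i``.  Valid generative
    models require every cluster to be nonempty; assignments with empty
    clusters are tolerated (with a warning) because hill climbing may
    transiently propose them.
    """

    n: int
    K: int
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.shape != (self.n,):
            raise ValueError(f"labels must have shape ({self.n},)")
        if self.K < 1 or self.K > self.n:
            raise ValueError("need 1 <= K <= n")
        if labels.min() < 0 or labels.max() >= self.K:
            raise ValueError(f"cluster labels must lie in [0, {self.K})")
        object.__setattr__(self, "labels", labels)
        if np.any(self.sizes == 0):
            warnings.warn("cluster assignment has empty clusters", stacklevel=2)

    @property
    def sizes(self) -> np.ndarray:
        """Cluster sizes ``#V_k``."""
        return np.bincount(self.labels, minlength=self.K)

    @property
    def relative_sizes(self) -> np.ndarray:
        """Relative sizes ``alpha_k = #V_k / n``."""
        return self.sizes / self.n

    @classmethod
    def balanced(cls, n: int, K: int) -> "ClusterAssignment":
        """Contiguous blocks of balanced-as-possible sizes."""
        base, extra = divmod(n, K)
        sizes = [base + (1 if k < extra else 0) for k in range(K)]
        labels = np.repeat(np.arange(K), sizes)
        return cls(n=n, K=K, labels=labels)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def relabelled_by_size(self) -> "ClusterAssignment":
        """Relabel clusters by decreasing size (ties: smaller old label first)."""
        order = sorted(range(self.K), key=lambda k: (-self.sizes[k], k))
        new_of_old = np.empty(self.K, dtype=np.int64)
        new_of_old[order] = np.arange(self.K)
        return ClusterAssignment(self.n, self.K, new_of_old[self.labels])


def _validate_rows(p: np.ndarray, what: str = "p") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2:
        raise ValueError(f"{what} must be a matrix")
    if np.any(p < 0):
        raise ValueError(f"{what} has negative entries")
    rows = p.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > _ROW_SUM_TOL):
        bad = int(np.argmax(np.abs(rows - 1.0)))
        raise ValueError(f"row {bad} of {what} sums to {rows[bad]:.12g}, not 1")
    return p / rows[:, None]  # renormalize to machine precision


@dataclass(frozen=True)
class BMCModel:
    """A 1st-order block Markov chain: cluster assignment plus ``K x K`` p."""

    assignment: ClusterAssignment
    p: np.ndarray

    def __post_init__(self):
        p = _validate_rows(self.p)
        if p.shape != (self.assignment.K, self.assignment.K):
            raise ValueError(
                f"p has shape {p.shape}, expected "
                f"({self.assignment.K}, {self.assignment.K})"
            )
        if np.any(self.assignment.sizes == 0):
            raise ValueError("generative models require all clusters nonempty")
        object.__setattr__(self, "p", p)

    @property
    def n(self) -> int:
        return self.assignment.n

    @property
    def K(self) -> int:
        return self.assignment.K

    @property
    def is_zeroth_order(self) -> bool:
        """True when all rows of ``p`` are equal (i.i.d. sampling)."""
        return bool(np.allclose(self.p, self.p[0][None, :], atol=1e-12))

    def transition_matrix(self) -> np.ndarray:
        return state_transition_matrix(self)

    def cluster_equilibrium(self) -> np.ndarray:
        return cluster_equilibrium(self.p)

    def state_equilibrium(self) -> np.ndarray:
        return state_equilibrium(self)


@dataclass(frozen=True)
class HigherOrderClusterModel:
    """An ``r``-th order clustered Markov chain.

    The law of the next observation depends on the clusters of the last ``r``
    observations only, and the state is uniform within the destination
    cluster.  ``q`` has one row per length-``r`` cluster context (contexts in
    lexicographic order, oldest symbol most significant) and ``K`` columns.
    ``r=1`` reduces to :class:`BMCModel`; ``r=0`` to the 0th-order BMC.
    """

    assignment: ClusterAssignment
    order: int
    q: np.ndarray

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be >= 0")
        K = self.assignment.K
        q = _validate_rows(self.q, "q")
        if q.shape != (K**self.order, K):
            raise ValueError(f"q has shape {q.shape}, expected ({K**self.order}, {K})")
        if np.any(self.assignment.sizes == 0):
            raise ValueError("generative models require all clusters nonempty")
        object.__setattr__(self, "q", q)

    @property
    def n(self) -> int:
        return self.assignment.n

    @property
    def K(self) -> int:
        return self.assignment.K

    def context_index(self, context) -> int:
        """Lexicographic index of a length-``r`` cluster context."""
        context = tuple(context)
        if len(context) != self.order:
            raise ValueError(f"context must have length {self.order}")
        idx = 0
        for c in context:
            idx = idx * self.K + int(c)
        return idx

    def as_bmc(self) -> BMCModel:
        if self.order != 1:
            raise ValueError("only r=1 models reduce to a 1st-order BMC")
        return BMCModel(self.assignment, self.q)


def make_bmc(assignment: ClusterAssignment, p) -> BMCModel:
    """Construct and validate a 1st-order BMC."""
    return BMCModel(assignment, np.asarray(p, dtype=float))


def make_zeroth_order(assignment: ClusterAssignment, eta) -> BMCModel:
    """A 0th-order BMC: all rows of ``p`` equal the distribution ``eta``."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (assignment.K,):
        raise ValueError(f"eta must have length {assignment.K}")
    if np.any(eta < 0) or abs(eta.sum() - 1.0) > _ROW_SUM_TOL:
        raise ValueError("eta must be a probability distribution")
    return BMCModel(assignment, np.tile(eta / eta.sum(), (assignment.K, 1)))


def make_higher_order(assignment: ClusterAssignment, q, r: int) -> HigherOrderClusterModel:
    """Construct and validate an ``r``-th order clustered Markov chain."""
    return HigherOrderClusterModel(assignment, int(r), np.asarray(q, dtype=float))


def state_transition_matrix(model: BMCModel) -> np.ndarray:
    """The full ``n x n`` kernel ``P_ij = p_{sigma(i), sigma(j)} / #V_{sigma(j)}``."""
    labels = model.assignment.labels
    sizes = model.assignment.sizes
    return model.p[np.ix_(labels, labels)] / sizes[labels][None, :]


def _check_ergodic(p: np.ndarray, warn_periodic: bool = True) -> None:
    g = nx.DiGraph((int(i), int(j)) for i, j in zip(*np.nonzero(p > 0)))
    g.add_nodes_from(range(p.shape[0]))
    if not nx.is_strongly_connected(g):
        comps = [sorted(c) for c in nx.strongly_connected_components(g)]
        raise ValueError(
            "transition matrix is not irreducible; strongly connected "
            f"components: {comps}"
        )
    if warn_periodic and not nx.is_aperiodic(g):
        warnings.warn(
            "transition matrix is periodic; the stationary equation is solved "
            "anyway but time averages, not limits, are the right reading",
            stacklevel=3,
        )


def cluster_equilibrium(p) -> np.ndarray:
    """Stationary distribution ``pi`` of the cluster chain: ``pi p = pi``.

    ``p`` must be irreducible; a periodic chain only triggers a warning.
    Solved by a dense linear solve for K <= 64 and by power iteration above.
    """
    p = _validate_rows(np.asarray(p, dtype=float))
    K = p.shape[0]
    _check_ergodic(p)
    if K <= 64:
        a = p.T - np.eye(K)
        a[-1, :] = 1.0
        b = np.zeros(K)
        b[-1] = 1.0
        pi = np.linalg.solve(a, b)
    else:
        pi = np.full(K, 1.0 / K)
        for _ in range(100_000):
            new = pi @ p
            if np.abs(new - pi).max() < 1e-14:
                pi = new
                break
            pi = new
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    # polish: one extra application keeps the residual at machine precision
    resid = np.abs(pi @ p - pi).max()
    if resid > 1e-12:
        for _ in range(1000):
            pi = pi @ p
            pi /= pi.sum()
            if np.abs(pi @ p - pi).max() <= 1e-13:
                break
    return pi


def state_equilibrium(model: BMCModel) -> np.ndarray:
    """Stationary distribution over states: ``Pi_j = pi_{sigma(j)} / #V_{sigma(j)}``."""
    pi = cluster_equilibrium(model.p)
    labels = model.assignment.labels
    sizes = model.assignment.sizes
    return pi[labels] / sizes[labels]


def perturb(base, delta, epsilon: float) -> np.ndarray:
    """Convex mixture ``(1 - eps) * base + eps * delta`` of stochastic kernels."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    base = np.asarray(base, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if base.shape != delta.shape:
        raise ValueError("base and delta must have the same shape")
    return (1.0 - epsilon) * base + epsilon * delta


# -- plain-text model serialization ------------------------------------------

def write_model(model, file) -> None:
    """Write a model as plain text: header ``n K r``, then the assignment as
    ``state<TAB>cluster`` lines, then the q rows in context-lexicographic
    order."""
    if isinstance(model, BMCModel):
        assignment, r, q = model.assignment, 1, model.p
    else:
        assignment, r, q = model.assignment, model.order, model.q
    own = isinstance(file, (str, bytes))
    fh = open(file, "w") if own else file
    try:
        fh.write(f"{assignment.n} {assignment.K} {r}\n")
        for i, k in enumerate(assignment.labels):
            fh.write(f"{i}\t{int(k)}\n")
        for row in np.atleast_2d(q):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    finally:
        if own:
            fh.close()


def read_model(file):
    """Read a model written by :func:`write_model`.

    Returns a :class:`BMCModel` when ``r == 1`` and a
    :class:`HigherOrderClusterModel` otherwise.
    """
    own = isinstance(file, (str, bytes))
    fh = open(file) if own else file
    try:
        n, K, r = (int(tok) for tok in fh.readline().split())
        labels = np.empty(n, dtype=np.int64)
        for _ in range(n):
            i, k = fh.readline().split("\t")
            labels[int(i)] = int(k)
        q = np.array(
            [[float(v) for v in fh.readline().split()] for _ in range(K**r)]
        )
    finally:
        if own:
            fh.close()
    assignment = ClusterAssignment(n=n, K=K, labels=labels)
    if r == 1:
        return BMCModel(assignment, q)
    return HigherOrderClusterModel(assignment, r, q)
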