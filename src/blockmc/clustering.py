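"""Block Markov chain estimation.

The fitting algorithm has two steps.  *Spectral initialization* embeds each
state by its left and right rows of the rank-K truncated SVD of the (trimmed)
transition-count matrix — states that transition to and from similar places
land close together — and runs k-means on that embedding.  *Likelihood
improvement* then hill-climbs the BMC log-likelihood

.. math::

    \\hat{\\mathcal L}(X_{1:\\ell} \\mid p, \\sigma)
    = \\sum_{t=1}^{\\ell-1}
      \\ln \\frac{p_{\\sigma(X_t), \\sigma(X_{t+1})}}{\\#V_{\\sigma(X_{t+1})}}

over single-state cluster moves, with ``p`` profiled out at its MLE.

The statsmodels-style front door is :class:`BlockMarkovChain` whose ``fit``
returns a :class:`BMCResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from . import empirics
from .models import ClusterAssignment
from .paths import SamplePath

__all__ = [
    "log_likelihood",
    "spectral_cluster",
    "improve",
    "fit",
    "BlockMarkovChain",
    "BMCResults",
]

NEG_INF = float("-inf")


def log_likelihood(path: SamplePath, p, assignment: ClusterAssignment) -> float:
    """BMC log-likelihood of a path, conditional on the first state.

    Returns ``-inf`` (as an explicit sentinel) when some observed transition
    has zero cluster probability.
    """
    if len(path) < 1:
        raise ValueError("empty path")
    p = np.asarray(p, dtype=float)
    labels = assignment.labels
    sizes = assignment.sizes
    i, j = path.transition_pairs()
    probs = p[labels[i], labels[j]]
    if np.any(probs <= 0.0):
        return NEG_INF
    return float(np.sum(np.log(probs)) - np.sum(np.log(sizes[labels[j]])))


def _profile_loglik(M: np.ndarray, sizes: np.ndarray) -> float:
    """Eq-9 log-likelihood with p profiled out at its MLE, from cluster counts.

    sum_kl M_kl ln M_kl - sum_k M_k. ln M_k. - sum_l M_.l ln #V_l, with the
    convention 0 ln 0 = 0.  Empty clusters receiving transitions are scored
    -inf (such assignments are invalid).
    """
    M = M.astype(float)
    rows = M.sum(axis=1)
    cols = M.sum(axis=0)
    if np.any((sizes == 0) & (cols > 0)):
        return NEG_INF
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(M > 0, M * np.log(M), 0.0).sum()
        t2 = np.where(rows > 0, rows * np.log(rows), 0.0).sum()
        pos = cols > 0
        t3 = float(np.sum(cols[pos] * np.log(sizes[pos])))
    return float(t1 - t2 - t3)


def spectral_cluster(
    N: empirics.FrequencyMatrix,
    K: int,
    seed: int = 0,
    restarts: int = 10,
) -> ClusterAssignment:
    """Spectral initialization on a (possibly trimmed) count matrix.

    Each non-trimmed state is embedded as the concatenation of its rows in
    ``U S`` and ``V S`` from the top-K SVD of the counts (2K coordinates) and
    the embedding is clustered with k-means (k-means++ init, best of
    ``restarts`` runs).  Trimmed states join the largest cluster; labels are
    relabelled by decreasing cluster size.
    """
    n = N.n
    trimmed = list(getattr(N, "trimmed", ()))
    active = np.ones(n, dtype=bool)
    active[trimmed] = False
    n_active = int(active.sum())
    if K > n_active:
        raise ValueError(f"K={K} exceeds the {n_active} non-trimmed states")

    A = N.toarray().astype(float)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    k_eff = min(K, max(rank, 1))
    if k_eff < K:
        warnings.warn(
            f"count matrix has rank {rank} < K={K}; "
            "clustering on the available components",
            stacklevel=2,
        )
    emb = np.hstack([U[:, :k_eff] * s[:k_eff], Vt[:k_eff, :].T * s[:k_eff]])

    km = KMeans(
        n_clusters=K, init="k-means++", n_init=restarts, random_state=seed
    ).fit(emb[active])
    labels = np.empty(n, dtype=np.int64)
    labels[active] = km.labels_
    if trimmed:
        largest = int(np.bincount(km.labels_, minlength=K).argmax())
        labels[~active] = largest
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # transiently empty clusters allowed
        assignment = ClusterAssignment(n=n, K=K, labels=labels)
    return assignment.relabelled_by_size()


@dataclass
class BMCResults:
    """Result of a BMC fit: assignment, cluster matrix, and diagnostics.

    Attributes
    ----------
    assignment : ClusterAssignment
        Final cluster assignment.
    p : ndarray
        ``K x K`` profile-MLE cluster transition matrix.
    cluster_count_matrix : ndarray
        The ``K x K`` transition counts behind ``p``.
    trace : list of float
        Profile log-likelihood after each improvement sweep; non-decreasing.
    """

    assignment: ClusterAssignment
    p: np.ndarray
    cluster_count_matrix: np.ndarray
    trace: list = field(default_factory=list)
    seed: int | None = None
    gamma: int = 0
    iterations: int = 0
    path: SamplePath | None = None

    @property
    def K(self) -> int:
        return self.assignment.K

    @property
    def n(self) -> int:
        return self.assignment.n

    @property
    def llf(self) -> float:
        """Final log-likelihood (Eq-9 value at the profile MLE)."""
        return self.trace[-1] if self.trace else NEG_INF

    def transition_matrix(self) -> np.ndarray:
        """The fitted ``n x n`` kernel ``p_hat[sigma(i), sigma(j)] / #V``."""
        labels = self.assignment.labels
        sizes = self.assignment.sizes
        return self.p[np.ix_(labels, labels)] / sizes[labels][None, :]

    def to_model(self):
        from .models import BMCModel

        return BMCModel(self.assignment, self.p)

    def clustered_path(self) -> SamplePath:
        if self.path is None:
            raise ValueError("results carry no path")
        return self.path.map_states(self.assignment.labels, self.K)

    def select_order(self, r_max: int = 4):
        from .evaluation import select_order

        return select_order(self.clustered_path(), self.K, r_max=r_max)

    def summary(self) -> str:
        lines = [
            "Block Markov chain fit",
            "=" * 46,
            f"states n            : {self.n}",
            f"clusters K          : {self.K}",
            f"trimmed states Gamma: {self.gamma}",
            f"improvement sweeps  : {self.iterations}",
            f"log-likelihood      : {self.llf:.4f}",
            f"seed                : {self.seed}",
            "",
            "cluster sizes (1-based labels):",
        ]
        for k, size in enumerate(self.assignment.sizes, start=1):
            lines.append(f"  cluster {k}: {size} states")
        lines.append("")
        lines.append("cluster transition matrix p_hat:")
        for row in self.p:
            lines.append("  " + "  ".join(f"{v:6.4f}" for v in row))
        return "\n".join(lines)

    def save(self, prefix: str) -> None:
        """Serialize as assignment TSV, p CSV, and a JSON provenance sidecar."""
        with open(f"{prefix}.assignment.tsv", "w") as fh:
            for i, k in enumerate(self.assignment.labels):
                fh.write(f"{i}\t{int(k)}\n")
        np.savetxt(f"{prefix}.p.csv", self.p, delimiter=",")
        with open(f"{prefix}.json", "w") as fh:
            json.dump(
                {
                    "n": self.n,
                    "K": self.K,
                    "gamma": self.gamma,
                    "seed": self.seed,
                    "iterations": self.iterations,
                    "trace": list(map(float, self.trace)),
                },
                fh,
                indent=2,
            )


def improve(
    path: SamplePath,
    assignment: ClusterAssignment,
    iterations: int = 10,
    seed: int = 0,
) -> BMCResults:
    """Hill-climb the profile log-likelihood by single-state cluster moves.

    Up to ``iterations`` sweeps; within each sweep states are visited in a
    seed-fixed shuffled order and the best strictly-improving move per state
    is applied.  Moves that would empty a cluster are rejected.  Stops early
    after a sweep with no move.
    """
    N = empirics.frequency_matrix(path)
    csr = N.counts.tocsr()
    csc = N.counts.tocsc()
    K = assignment.K
    labels = assignment.labels.copy()
    sizes = np.bincount(labels, minlength=K)
    M = empirics.cluster_counts(N, assignment).astype(np.int64)

    rng = np.random.default_rng(seed)
    trace = [_profile_loglik(M, sizes)]
    sweeps_done = 0
    for _ in range(iterations):
        moved = False
        for i in rng.permutation(assignment.n):
            a = int(labels[i])
            if sizes[a] <= 1:
                continue  # any move would empty cluster a
            row = csr[i]
            col = csc[:, i]
            out_c = np.bincount(
                labels[row.indices], weights=row.data, minlength=K
            )
            in_c = np.bincount(
                labels[col.indices], weights=col.data, minlength=K
            )
            nii = float(csr[i, i])
            out_c[a] -= nii
            in_c[a] -= nii
            base = M.astype(float)
            base[a, :] -= out_c
            base[:, a] -= in_c
            base[a, a] -= nii
            cur = _profile_loglik(M, sizes)
            best_gain, best_b, best_M = 0.0, None, None
            for b in range(K):
                if b == a:
                    continue
                cand = base.copy()
                cand[b, :] += out_c
                cand[:, b] += in_c
                cand[b, b] += nii
                s2 = sizes.copy()
                s2[a] -= 1
                s2[b] += 1
                gain = _profile_loglik(cand, s2) - cur
                if gain > best_gain + 1e-12:
                    best_gain, best_b, best_M = gain, b, cand
            if best_b is not None:
                labels[i] = best_b
                sizes[a] -= 1
                sizes[best_b] += 1
                M = np.rint(best_M).astype(np.int64)
                moved = True
        sweeps_done += 1
        trace.append(_profile_loglik(M, sizes))
        if not moved:
            break

    final = ClusterAssignment(n=assignment.n, K=K, labels=labels)
    sm = M.astype(float)
    rows = sm.sum(axis=1)
    p_hat = np.where(
        rows[:, None] > 0, sm / np.maximum(rows, 1)[:, None], 1.0 / K
    )
    return BMCResults(
        assignment=final,
        p=p_hat,
        cluster_count_matrix=M,
        trace=trace,
        seed=seed,
        iterations=sweeps_done,
        path=path,
    )


def fit(
    path: SamplePath,
    K: int,
    gamma: int = 0,
    iterations: int = 10,
    seed: int = 0,
    restarts: int = 10,
) -> BMCResults:
    """Full pipeline: counts -> trim -> spectral init -> likelihood improvement."""
    if len(path) < 2:
        raise ValueError("path must have at least 2 observations")
    N = empirics.frequency_matrix(path)
    trimmed = empirics.trim(N, gamma)
    init = spectral_cluster(trimmed, K, seed=seed, restarts=restarts)
    result = improve(path, init, iterations=iterations, seed=seed)
    result.gamma = gamma
    result.seed = seed
    return result


def heuristic_gamma(N: empirics.FrequencyMatrix) -> int:
    """Trim states whose degree exceeds 10x the median degree."""
    deg = N.degrees
    med = np.median(deg)
    return int(np.sum(deg > 10 * med)) if med > 0 else 0


class BlockMarkovChain:
    """Block Markov chain model for a discrete observation sequence.

    Parameters
    ----------
    path : SamplePath
        The observation sequence.
    K : int
        Number of clusters (kept fixed during fitting).
    gamma : int, default 0
        Number of highest-degree states to trim before the spectral step.

    Examples
    --------
    >>> from blockmc import BlockMarkovChain, simulate
    >>> model = simulate.random_bmc(60, 3, separation=1.0, seed=0)
    >>> path = simulate.sample_model_path(
    ...     model, simulate.SimulationConfig(length=20000, seed=1))
    >>> res = BlockMarkovChain(path, K=3).fit(seed=0)
    >>> res.p.shape
    (3, 3)
    """

    def __init__(self, path: SamplePath, K: int, gamma: int = 0):
        self.path = path
        self.K = int(K)
        self.gamma = int(gamma)

    @classmethod
    def from_fasta(cls, fasta, K: int, frame: int = 0, gamma: int = 0):
        """Build a codon-path model from FASTA nucleotide records."""
        from .sequence_io import read_fasta_codons

        return cls(read_fasta_codons(fasta, frame=frame), K=K, gamma=gamma)

    @classmethod
    def from_trajectory(cls, coords, grid, K: int, gamma: int = 0,
                        drop_self_jumps: bool = True):
        """Build a model from a 2-D coordinate trajectory via grid binning."""
        from .sequence_io import grid_bin_trajectory, remove_self_transitions

        path = grid_bin_trajectory(coords, grid)
        if drop_self_jumps:
            path = remove_self_transitions(path)
        return cls(path, K=K, gamma=gamma)

    def fit(self, seed: int = 0, iterations: int = 10, restarts: int = 10) -> BMCResults:
        return fit(
            self.path,
            self.K,
            gamma=self.gamma,
            iterations=iterations,
            seed=seed,
            restarts=restarts,
        )
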