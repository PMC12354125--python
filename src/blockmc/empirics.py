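"""Count statistics of a sample path.

Transition counts are stored sparsely (CSR) since real sequences are far
shorter than ``n^2``.  The module provides the empirical frequency matrix,
degree trimming, the normalized Laplacian, and the maximum-likelihood
transition estimators at state and cluster level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .models import ClusterAssignment
from .paths import SamplePath

__all__ = [
    "FrequencyMatrix",
    "TrimmedFrequencyMatrix",
    "frequency_matrix",
    "trim",
    "normalized_laplacian",
    "empirical_transition",
    "mle_cluster_transition",
    "mle_clustered_higher_order",
    "read_counts_mm",
    "write_counts_mm",
]


@dataclass(frozen=True)
class FrequencyMatrix:
    """Empirical transition counts ``N_ij`` of a path, plus its provenance."""

    counts: sp.csr_matrix
    source_length: int

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def toarray(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    @property
    def degrees(self) -> np.ndarray:
        """In-count plus out-count per state."""
        return (
            np.asarray(self.counts.sum(axis=1)).ravel()
            + np.asarray(self.counts.sum(axis=0)).ravel()
        )


@dataclass(frozen=True)
class TrimmedFrequencyMatrix(FrequencyMatrix):
    """Counts with the rows and columns of the trimmed states zeroed."""

    trimmed: tuple = ()


def frequency_matrix(path: SamplePath) -> FrequencyMatrix:
    """Count transitions ``N_ij = #{t : X_t = i, X_{t+1} = j}`` within segments."""
    i, j = path.transition_pairs()
    if i.size == 0:
        raise ValueError("path has no usable transitions")
    counts = sp.coo_matrix(
        (np.ones(i.size, dtype=np.int64), (i, j)), shape=(path.n, path.n)
    ).tocsr()
    return FrequencyMatrix(counts=counts, source_length=len(path))


def trim(N: FrequencyMatrix, gamma: int) -> TrimmedFrequencyMatrix:
    """Zero the rows and columns of the ``gamma`` highest-degree states.

    Degree is in-count plus out-count; ties are broken toward the smaller
    state index.  ``gamma = 0`` leaves the counts unchanged.
    """
    n = N.n
    if not 0 <= gamma <= n:
        raise ValueError("need 0 <= gamma <= n")
    # argsort(-degrees, stable) resolves ties in increasing index order;
    # previously trimmed states keep priority so re-trimming is a no-op
    existing = [int(s) for s in getattr(N, "trimmed", ())]
    order = existing + [
        int(s) for s in np.argsort(-N.degrees, kind="stable")
        if int(s) not in set(existing)
    ]
    trimmed = tuple(order[:gamma])
    keep = np.ones(n, dtype=bool)
    keep[list(trimmed)] = False
    mask = sp.diags(keep.astype(np.int64), dtype=np.int64)
    counts = (mask @ N.counts @ mask).tocsr()
    counts.eliminate_zeros()
    return TrimmedFrequencyMatrix(
        counts=counts, source_length=N.source_length, trimmed=trimmed
    )


def normalized_laplacian(N: FrequencyMatrix) -> sp.csr_matrix:
    """``L_ij = N_ij / sqrt(rowsum_i * colsum_j)`` on the support, 0 elsewhere.

    A nonzero ``N_ij`` forces positive row-``i`` and column-``j`` sums, so no
    0/0 can occur.
    """
    counts = N.counts.tocoo()
    if counts.nnz == 0:
        return sp.csr_matrix(N.counts.shape)
    rows = np.asarray(N.counts.sum(axis=1)).ravel()
    cols = np.asarray(N.counts.sum(axis=0)).ravel()
    data = counts.data / np.sqrt(rows[counts.row] * cols[counts.col])
    return sp.csr_matrix((data, (counts.row, counts.col)), shape=N.counts.shape)


def empirical_transition(N: FrequencyMatrix, smoothing: float = 0.0) -> np.ndarray:
    """Row-normalized counts: the unconstrained Markov-chain MLE.

    Rows with no observations fall back to the uniform row ``1/n`` (the
    no-information default).  ``smoothing`` adds a constant to every count
    before normalization, used when a fitted model must score unseen holdout
    transitions.
    """
    counts = N.toarray().astype(float) + smoothing
    rows = counts.sum(axis=1)
    out = np.empty_like(counts)
    zero = rows == 0
    out[zero] = 1.0 / N.n
    out[~zero] = counts[~zero] / rows[~zero, None]
    return out


def write_counts_mm(N: FrequencyMatrix, file) -> None:
    """Write counts in MatrixMarket coordinate format (1-based, integer)."""
    from scipy.io import mmwrite

    mmwrite(file, N.counts.tocoo(), field="integer",
            comment=f"source_length={N.source_length}")


def read_counts_mm(file, source_length: int | None = None) -> FrequencyMatrix:
    """Read a MatrixMarket count matrix written by :func:`write_counts_mm`.

    The source length defaults to ``total + 1`` (an unbroken path) when the
    file carries no record of it.
    """
    from scipy.io import mmread

    counts = sp.csr_matrix(mmread(file)).astype(np.int64)
    if source_length is None:
        source_length = int(counts.sum()) + 1
    return FrequencyMatrix(counts=counts, source_length=source_length)


def cluster_counts(N: FrequencyMatrix, assignment: ClusterAssignment) -> np.ndarray:
    """Aggregate state counts into ``K x K`` cluster counts ``M_kl``."""
    K = assignment.K
    coo = N.counts.tocoo()
    M = np.zeros((K, K), dtype=np.int64)
    np.add.at(M, (assignment.labels[coo.row], assignment.labels[coo.col]), coo.data)
    return M


def mle_cluster_transition(
    path: SamplePath, assignment: ClusterAssignment, smoothing: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Profile MLE of the cluster matrix ``p`` given an assignment.

    Returns ``(p_hat, M)`` where ``M_kl`` sums the transition counts between
    the clusters and ``p_hat`` is the row-normalized (optionally smoothed)
    ``M`` with uniform fallback for empty rows.
    """
    M = cluster_counts(frequency_matrix(path), assignment)
    sm = M.astype(float) + smoothing
    rows = sm.sum(axis=1)
    p_hat = np.empty_like(sm)
    zero = rows == 0
    p_hat[zero] = 1.0 / assignment.K
    p_hat[~zero] = sm[~zero] / rows[~zero, None]
    return p_hat, M


def _context_counts(path: SamplePath, K: int, r: int) -> np.ndarray:
    """Counts of (length-r context, next symbol) over within-segment windows."""
    C = np.zeros((K**r, K), dtype=np.int64)
    powers = K ** np.arange(r - 1, -1, -1) if r > 0 else None
    for seg in path.segments():
        if seg.size <= r:
            continue
        if r == 0:
            np.add.at(C[0], seg, 1)
            continue
        m = seg.size - r
        ctx = np.zeros(m, dtype=np.int64)
        for i in range(r):
            ctx += seg[i : i + m] * powers[i]
        np.add.at(C, (ctx, seg[r:]), 1)
    return C


def mle_clustered_higher_order(
    path: SamplePath, K: int, r: int, smoothing: float = 0.0
) -> np.ndarray:
    """MLE of an ``r``-th order chain over a clustered path in ``[0, K)``.

    For ``r = 0`` this is the empirical marginal over all symbols; for
    ``r >= 1`` each observed context row is count-normalized, and contexts
    never seen get the uniform row.
    """
    if len(path) <= r:
        raise ValueError(f"path of length {len(path)} cannot fit order r={r}")
    C = _context_counts(path, K, r).astype(float) + smoothing
    rows = C.sum(axis=1)
    out = np.empty_like(C)
    zero = rows == 0
    out[zero] = 1.0 / K
    out[~zero] = C[~zero] / rows[~zero, None]
    return out
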