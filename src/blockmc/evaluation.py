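"""Model comparison and diagnostics.

Holdout KL-divergence-rate differences, CAIC order selection for the
clustered sequence, degrees-of-freedom bookkeeping, and the misclassification
and estimation-error metrics used in the synthetic experiments.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import clustering, empirics
from .models import BMCModel, ClusterAssignment, state_transition_matrix
from .paths import SamplePath

__all__ = [
    "kl_rate_difference",
    "holdout_compare",
    "ComparisonReport",
    "caic",
    "select_order",
    "OrderSelectionResult",
    "degrees_of_freedom",
    "misclassification_rate",
    "estimation_error",
    "FirstOrderBMCProcedure",
    "ZerothOrderBMCProcedure",
    "EmpiricalProcedure",
]


def _as_kernel(model, n: int) -> np.ndarray:
    """Coerce a scoring model into an ``n x n`` transition kernel."""
    if isinstance(model, BMCModel):
        return state_transition_matrix(model)
    if isinstance(model, clustering.BMCResults):
        return model.transition_matrix()
    kernel = np.asarray(model, dtype=float)
    if kernel.shape != (n, n):
        raise ValueError(f"scoring model must be {n} x {n}")
    return kernel


def _log_terms(path: SamplePath, P, Q) -> np.ndarray:
    """Per-transition log-likelihood-ratio terms ln P(x_t -> x_{t+1}) - ln Q."""
    Pk = _as_kernel(P, path.n)
    Qk = _as_kernel(Q, path.n)
    i, j = path.transition_pairs()
    pv = Pk[i, j]
    qv = Qk[i, j]
    bad = (pv <= 0) | (qv <= 0)
    if np.any(bad):
        offending = list(zip(i[bad][:5].tolist(), j[bad][:5].tolist()))
        warnings.warn(
            f"zero transition probability at observed transitions {offending}; "
            "the KL rate difference is infinite",
            stacklevel=3,
        )
        terms = np.empty(pv.size)
        with np.errstate(divide="ignore"):
            terms = np.log(pv) - np.log(qv)
        return terms
    return np.log(pv) - np.log(qv)


def kl_rate_difference(path: SamplePath, P, Q) -> float:
    """Rescaled log-likelihood ratio ``(1/l') [ln P(path) - ln Q(path)]``.

    Path probabilities are conditional on the first state (product of
    transition probabilities); ``l'`` is the number of scored transitions.
    Estimates the KL-divergence-rate difference between the models and is
    ``+inf``/``-inf`` when one model assigns zero probability to an observed
    transition.
    """
    terms = _log_terms(path, P, Q)
    if terms.size == 0:
        raise ValueError("path has no usable transitions")
    return float(terms.mean())


@dataclass(frozen=True)
class ComparisonReport:
    """Holdout comparison of two fitting procedures.

    ``ci_low``/``ci_high`` are circular block-bootstrap percentile bounds on
    the validation half (a bootstrap CI, not an analytic bound).
    """

    dhat: float
    split_index: int
    ci_low: float
    ci_high: float
    model_p: str
    model_q: str
    smoothing: float
    n_boot: int
    block_length: int

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0

    def __str__(self) -> str:
        return (
            f"D_hat({self.model_p} vs {self.model_q}) = {self.dhat:.6g}  "
            f"[bootstrap 95% CI: {self.ci_low:.6g}, {self.ci_high:.6g}]"
        )


def _block_bootstrap_ci(
    terms: np.ndarray, n_boot: int, block_length: int, seed: int, level: float
) -> tuple[float, float]:
    """Circular block bootstrap of the mean of a stationary series."""
    T = terms.size
    L = max(1, min(block_length, T))
    n_blocks = math.ceil(T / L)
    rng = np.random.default_rng(seed)
    starts = rng.integers(T, size=(n_boot, n_blocks))
    offsets = np.arange(L)
    idx = (starts[:, :, None] + offsets[None, None, :]) % T
    samples = terms[idx.reshape(n_boot, -1)[:, :T]]
    means = samples.mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def holdout_compare(
    path: SamplePath,
    fit_p,
    fit_q,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    smoothing: float = 0.5,
) -> ComparisonReport:
    """Fit two procedures on the first half of a path, compare on the second.

    ``fit_p``/``fit_q`` are callables taking the training :class:`SamplePath`
    and returning a scoring model (anything :func:`kl_rate_difference`
    accepts).  The returned report carries the holdout KL-rate difference and
    a circular block-bootstrap CI over the validation transitions (block
    length ``ceil(sqrt(l/2))``).
    """
    ell = len(path)
    if ell < 4:
        raise ValueError("need at least 4 observations to split")
    half = ell // 2
    train = SamplePath(
        path.states[:half], n=path.n, breaks=tuple(b for b in path.breaks if b < half)
    )
    valid = SamplePath(
        path.states[half:],
        n=path.n,
        breaks=tuple(b - half for b in path.breaks if b > half),
    )
    model_p = fit_p(train)
    model_q = fit_q(train)
    terms = _log_terms(valid, model_p, model_q)
    dhat = float(terms.mean())
    block = math.ceil(math.sqrt(ell / 2))
    if np.all(np.isfinite(terms)):
        lo, hi = _block_bootstrap_ci(terms, n_boot, block, seed, level)
    else:
        lo, hi = dhat, dhat
    return ComparisonReport(
        dhat=dhat,
        split_index=half,
        ci_low=min(lo, dhat),
        ci_high=max(hi, dhat),
        model_p=getattr(fit_p, "name", repr(fit_p)),
        model_q=getattr(fit_q, "name", repr(fit_q)),
        smoothing=smoothing,
        n_boot=n_boot,
        block_length=block,
    )


# -- fitting procedures usable with holdout_compare ---------------------------

class FirstOrderBMCProcedure:
    """Fit a 1st-order BMC (spectral + improvement); score with smoothed p."""

    def __init__(self, K, gamma=0, iterations=10, seed=0, smoothing=0.5):
        self.K, self.gamma, self.iterations = K, gamma, iterations
        self.seed, self.smoothing = seed, smoothing
        self.name = f"BMC(K={K}, r=1)"

    def __call__(self, train: SamplePath) -> np.ndarray:
        res = clustering.fit(
            train, self.K, gamma=self.gamma,
            iterations=self.iterations, seed=self.seed,
        )
        p_hat, _ = empirics.mle_cluster_transition(
            train, res.assignment, smoothing=self.smoothing
        )
        labels = res.assignment.labels
        sizes = res.assignment.sizes
        return p_hat[np.ix_(labels, labels)] / sizes[labels][None, :]


class ZerothOrderBMCProcedure:
    """Fit the clusters, then score with the (smoothed) i.i.d. cluster law."""

    def __init__(self, K, gamma=0, iterations=10, seed=0, smoothing=0.5):
        self.K, self.gamma, self.iterations = K, gamma, iterations
        self.seed, self.smoothing = seed, smoothing
        self.name = f"BMC(K={K}, r=0)"

    def __call__(self, train: SamplePath) -> np.ndarray:
        res = clustering.fit(
            train, self.K, gamma=self.gamma,
            iterations=self.iterations, seed=self.seed,
        )
        labels = res.assignment.labels
        sizes = res.assignment.sizes
        counts = np.bincount(labels[train.states], minlength=self.K).astype(float)
        eta = (counts + self.smoothing) / (counts + self.smoothing).sum()
        row = eta[labels] / sizes[labels]
        return np.tile(row, (train.n, 1))


class EmpiricalProcedure:
    """The unconstrained Markov MLE with additive smoothing."""

    def __init__(self, smoothing=0.5):
        self.smoothing = smoothing
        self.name = "Empirical"

    def __call__(self, train: SamplePath) -> np.ndarray:
        return empirics.empirical_transition(
            empirics.frequency_matrix(train), smoothing=self.smoothing
        )


# -- CAIC order selection -----------------------------------------------------

def clustered_log_likelihood(path: SamplePath, K: int, r: int) -> float:
    """Conditional log-likelihood of the plug-in order-``r`` MLE.

    Positions ``r+1 .. l`` contribute (all positions for ``r = 0``, as
    marginal terms); within each observed context the plug-in probabilities
    are the count-normalized frequencies, so every scored term is positive.
    """
    C = empirics._context_counts(path, K, r).astype(float)
    rows = C.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(C > 0, C * (np.log(C) - np.log(rows)), 0.0).sum()
    return float(ll)


def caic(path: SamplePath, K: int, r: int) -> float:
    """Consistent AIC of the order-``r`` fit to a clustered path.

    ``-2 lnL + 2 DF(K, r) (1 + ln(l - r))`` with ``DF(K, r) = K^r (K - 1)``.
    """
    ell = len(path)
    if ell <= r:
        raise ValueError(f"path of length {ell} cannot fit order r={r}")
    ll = clustered_log_likelihood(path, K, r)
    df = degrees_of_freedom(None, K, order="clustered", r=r)
    return float(-2.0 * ll + 2.0 * df * (1.0 + math.log(ell - r)))


@dataclass(frozen=True)
class OrderSelectionResult:
    """CAIC values over candidate orders and the selected minimizer."""

    orders: tuple
    caic_values: tuple
    dfs: tuple
    selected: int

    def to_frame(self) -> pd.DataFrame:
        best = min(self.caic_values)
        return pd.DataFrame(
            {
                "r": self.orders,
                "CAIC": self.caic_values,
                "DF": self.dfs,
                "increase_vs_best_pct": [
                    100.0 * (v - best) / abs(best) if best != 0 else 0.0
                    for v in self.caic_values
                ],
            }
        )

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False)


def select_order(path: SamplePath, K: int, r_max: int = 4) -> OrderSelectionResult:
    """CAIC for ``r = 0 .. r_max``; ties broken toward the smaller order."""
    if len(path) <= r_max:
        raise ValueError("path too short for the requested r_max")
    orders = tuple(range(r_max + 1))
    values = tuple(caic(path, K, r) for r in orders)
    dfs = tuple(
        degrees_of_freedom(None, K, order="clustered", r=r) for r in orders
    )
    selected = orders[int(np.argmin(values))]  # argmin takes the first minimum
    return OrderSelectionResult(orders, values, dfs, selected)


def degrees_of_freedom(n, K: int, order="first", r: int | None = None) -> int:
    """Degrees of freedom of the constrained models.

    ``order="zeroth"``: ``n + K - 1`` (assignment plus the i.i.d. cluster
    law); ``order="first"``: ``n + K(K - 1)``; ``order="clustered"`` with
    ``r``: ``K^r (K - 1)``, the free parameters of an order-``r`` chain on
    ``K`` symbols.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if order == "clustered":
        if r is None or r < 0:
            raise ValueError("clustered DF needs an order r >= 0")
        return int(K**r * (K - 1))
    if n is None or K > n:
        raise ValueError("need K <= n")
    if order == "zeroth":
        return int(n + K - 1)
    if order == "first":
        return int(n + K * (K - 1))
    raise ValueError(f"unknown order {order!r}")


# -- metrics ------------------------------------------------------------------

def misclassification_rate(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Fraction of mismatching states, minimized over cluster relabellings.

    Exhaustive over the ``K!`` permutations for ``K <= 6``, otherwise an
    optimal assignment on the confusion matrix.
    """
    if a.n != b.n:
        raise ValueError("assignments must cover the same states")
    K = max(a.K, b.K)
    confusion = np.zeros((K, K), dtype=np.int64)
    np.add.at(confusion, (a.labels, b.labels), 1)
    if K <= 6:
        best = max(
            sum(confusion[perm[j], j] for j in range(K))
            for perm in itertools.permutations(range(K))
        )
    else:
        ri, ci = linear_sum_assignment(-confusion)
        best = int(confusion[ri, ci].sum())
    return float(1.0 - best / a.n)


def estimation_error(P, P_hat) -> float:
    """Spectral-norm estimation error ``||P - P_hat||_2``."""
    P = np.asarray(P, dtype=float)
    P_hat = np.asarray(P_hat, dtype=float)
    if P.shape != P_hat.shape:
        raise ValueError("matrices must have the same shape")
    return float(np.linalg.norm(P - P_hat, 2))
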