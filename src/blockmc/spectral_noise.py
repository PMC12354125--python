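"""Spectral-noise diagnostics.

Under a block Markov chain, the leading ``K`` singular values of the count
matrix carry the signal while the remaining bulk behaves like noise whose
shape diagnoses model fit.  This module computes those bulk spectra for
``N/sqrt(n)`` and ``sqrt(n) L`` (L the normalized Laplacian), predicts the
bulk under a fitted model by Monte-Carlo simulation (a labelled stand-in for
a closed-form limit law, which is out of scope here), and fits the
quarter-circle reference density ``f(x) = (4 / (pi c^2)) sqrt(c^2 - x^2)``
expected for the Laplacian bulk of a 0th-order chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .empirics import FrequencyMatrix, frequency_matrix, normalized_laplacian
from .models import BMCModel
from .paths import SamplePath
from .simulate import SimulationConfig, sample_model_path

__all__ = [
    "NoiseSpectrum",
    "noise_singular_values",
    "frequency_noise",
    "laplacian_noise",
    "predicted_noise_distribution",
    "PredictedNoise",
    "QuarterCircleFit",
    "quarter_circle_fit",
    "spectrum_distance",
    "histogram",
]


@dataclass(frozen=True)
class NoiseSpectrum:
    """Bulk singular values of a scaled matrix, top ``excluded`` removed."""

    kind: str
    excluded: int
    values: np.ndarray
    n: int
    ell: int | None = None

    def __post_init__(self):
        values = np.sort(np.asarray(self.values, dtype=float))[::-1]
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)


def _singular_values(M) -> np.ndarray:
    if sp.issparse(M):
        M = np.asarray(M.todense())
    return np.linalg.svd(np.asarray(M, dtype=float), compute_uv=False)


def noise_singular_values(
    M, scale: float, exclude_top: int, kind: str = "custom", ell: int | None = None
) -> NoiseSpectrum:
    """Singular values of ``scale * M`` with the largest ``exclude_top`` removed."""
    svals = _singular_values(M) * scale
    if exclude_top > svals.size:
        raise ValueError("cannot exclude more values than exist")
    return NoiseSpectrum(
        kind=kind,
        excluded=exclude_top,
        values=svals[exclude_top:],
        n=M.shape[0],
        ell=ell,
    )


def frequency_noise(N: FrequencyMatrix, exclude_top: int) -> NoiseSpectrum:
    """Bulk of ``N / sqrt(n)``."""
    return noise_singular_values(
        N.counts, 1.0 / np.sqrt(N.n), exclude_top,
        kind="frequency-scaled", ell=N.source_length,
    )


def laplacian_noise(N: FrequencyMatrix, exclude_top: int) -> NoiseSpectrum:
    """Bulk of ``sqrt(n) * L`` with L the normalized Laplacian."""
    return noise_singular_values(
        normalized_laplacian(N), np.sqrt(N.n), exclude_top,
        kind="laplacian-scaled", ell=N.source_length,
    )


@dataclass(frozen=True)
class PredictedNoise:
    """Pooled Monte-Carlo noise spectra under a fitted model (both scalings)."""

    frequency: NoiseSpectrum
    laplacian: NoiseSpectrum
    reps: int
    seed: int


def predicted_noise_distribution(
    model: BMCModel, ell: int, reps: int = 20, seed: int = 0
) -> PredictedNoise:
    """Monte-Carlo predictor of the noise bulk under a fitted BMC.

    Simulates ``reps`` independent stationary paths of length ``ell`` from
    the model and pools the per-path bulk spectra (``exclude_top = K``) of
    both matrix scalings.  Deterministic given ``seed``.  This is a simulated
    stand-in for a limiting spectral law, suitable for the same histogram
    comparisons.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(2**31 - 1, size=reps)
    freq_vals, lap_vals = [], []
    for s in child_seeds:
        path = sample_model_path(model, SimulationConfig(length=ell, seed=int(s)))
        N = frequency_matrix(path)
        freq_vals.append(frequency_noise(N, model.K).values)
        lap_vals.append(laplacian_noise(N, model.K).values)
    return PredictedNoise(
        frequency=NoiseSpectrum(
            "frequency-scaled", model.K, np.concatenate(freq_vals), model.n, ell
        ),
        laplacian=NoiseSpectrum(
            "laplacian-scaled", model.K, np.concatenate(lap_vals), model.n, ell
        ),
        reps=reps,
        seed=seed,
    )


@dataclass(frozen=True)
class QuarterCircleFit:
    """Quarter-circle density on ``(0, c)``, moment-matched to a spectrum."""

    c: float

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        inside = (x >= 0) & (x <= self.c)
        out = np.zeros_like(x)
        out[inside] = (4.0 / (np.pi * self.c**2)) * np.sqrt(
            self.c**2 - x[inside] ** 2
        )
        return out

    def cdf(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), 0.0, self.c)
        z = x / self.c
        return (2.0 / np.pi) * (np.arcsin(z) + z * np.sqrt(1.0 - z**2))

    def ppf(self, q) -> np.ndarray:
        """Inverse CDF by bisection (used for drawing reference samples)."""
        q = np.asarray(q, dtype=float)
        lo = np.zeros_like(q)
        hi = np.full_like(q, self.c)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            below = self.cdf(mid) < q
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi)


def quarter_circle_fit(spectrum: NoiseSpectrum) -> QuarterCircleFit:
    """Moment-match the support ``c``: E[x^2] = c^2/4 implies c = 2 sqrt(E[x^2])."""
    values = spectrum.values
    if values.size == 0:
        raise ValueError("empty spectrum")
    m2 = float(np.mean(values**2))
    if m2 == 0.0:
        raise ValueError("all-zero spectrum cannot be moment-matched")
    return QuarterCircleFit(c=2.0 * np.sqrt(m2))


def spectrum_distance(empirical: NoiseSpectrum, reference) -> float:
    """Kolmogorov-Smirnov sup-distance to another spectrum or a fitted density."""
    if len(empirical) == 0:
        raise ValueError("empty spectrum")
    if isinstance(reference, QuarterCircleFit):
        return float(stats.ks_1samp(empirical.values, reference.cdf).statistic)
    if len(reference) == 0:
        raise ValueError("empty reference spectrum")
    return float(stats.ks_2samp(empirical.values, reference.values).statistic)


def histogram(spectrum: NoiseSpectrum, bins="fd") -> tuple[np.ndarray, np.ndarray]:
    """Density histogram with Freedman-Diaconis bins (edges are returned so
    figures are reproducible)."""
    density, edges = np.histogram(spectrum.values, bins=bins, density=True)
    return density, edges


def plot_noise(spectrum: NoiseSpectrum, fit: QuarterCircleFit | None = None,
               reference: NoiseSpectrum | None = None, out=None):
    """Histogram of a noise spectrum, optionally overlaying a reference.

    Returns the matplotlib axes; saves to ``out`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.hist(spectrum.values, bins="fd", density=True, alpha=0.6,
            label=f"empirical ({spectrum.kind})")
    if fit is not None:
        xs = np.linspace(0, fit.c * 1.05, 400)
        ax.plot(xs, fit.pdf(xs), "r-", label=f"quarter circle (c={fit.c:.3g})")
    if reference is not None:
        ax.hist(reference.values, bins="fd", density=True, histtype="step",
                label="Monte-Carlo prediction")
    ax.set_xlabel("singular value")
    ax.set_ylabel("density")
    ax.legend()
    if out is not None:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return ax
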