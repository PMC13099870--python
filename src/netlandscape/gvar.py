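"""Stationary moments, simulation and sum-score density of the GVAR process.

The lag-1 graphical VAR ``y_t = mu + B (y_{t-1} - mu) + eps_t`` with Gaussian
innovations is a stationary Gaussian process whenever the spectral radius of
``B`` is below one. Its stationary covariance solves the discrete Lyapunov
fixed point S = B S B' + Sigma, and the sum score 1'y is Gaussian with mean
``sum(mu)`` and variance ``1' S 1`` — so the landscape density is available in
closed form. A simulation + kernel-density route is kept as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .params import GVARParameters, spectral_radius

#: Residual tolerance for the Lyapunov fixed-point equation.
LYAPUNOV_TOL = 1e-8


@dataclass(frozen=True)
class StationaryMoments:
    """Stationary mean/covariance of a GVAR process and of its sum score."""

    mean: np.ndarray
    covariance: np.ndarray
    sum_mean: float
    sum_variance: float
    meta: dict = field(default_factory=dict, compare=False)


def stationary_moments(params: GVARParameters) -> StationaryMoments:
    """Solve the discrete Lyapunov equation for the stationary covariance."""
    rho = spectral_radius(params.beta)
    if rho >= 1.0:
        raise ValueError(f"process is nonstationary: spectral radius {rho:.4f} >= 1")
    s = linalg.solve_discrete_lyapunov(params.beta, params.sigma)
    s = 0.5 * (s + s.T)
    resid = np.max(np.abs(s - (params.beta @ s @ params.beta.T + params.sigma)))
    if resid > LYAPUNOV_TOL:
        raise RuntimeError(f"Lyapunov residual {resid:.2e} exceeds {LYAPUNOV_TOL:.0e}")
    ones = np.ones(params.n_vars)
    return StationaryMoments(
        mean=params.mu.copy(),
        covariance=s,
        sum_mean=float(params.mu.sum()),
        sum_variance=float(ones @ s @ ones),
        meta={"lyapunov_residual": float(resid), "spectral_radius": rho})


def simulate(
    params: GVARParameters,
    T: int,
    burn_in: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Iterate the GVAR recursion from y_0 = mu; returns a (T, n) array."""
    if T < 1:
        raise ValueError("T must be at least 1")
    rho = spectral_radius(params.beta)
    if rho >= 1.0:
        raise ValueError(f"process is nonstationary: spectral radius {rho:.4f} >= 1")
    rng = np.random.default_rng(seed)
    n = params.n_vars
    chol = np.linalg.cholesky(params.sigma)
    eps = rng.standard_normal((burn_in + T, n)) @ chol.T
    out = np.empty((T, n))
    dev = np.zeros(n)  # deviation from mu
    for t in range(burn_in + T):
        dev = params.beta @ dev + eps[t]
        if t >= burn_in:
            out[t - burn_in] = dev
    return out + params.mu


def default_sum_grid(
    moments: StationaryMoments, n_points: int = 201, span: float = 4.0
) -> np.ndarray:
    """Sum-score grid spanning mean +/- span standard deviations."""
    sd = float(np.sqrt(moments.sum_variance))
    return np.linspace(moments.sum_mean - span * sd, moments.sum_mean + span * sd,
                       n_points)


def sum_score_density(moments: StationaryMoments, grid: np.ndarray) -> np.ndarray:
    """Exact stationary density of the sum score on a grid (Gaussian)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if moments.sum_variance <= 0:
        raise ValueError("sum variance must be positive")
    return stats.norm.pdf(grid, loc=moments.sum_mean,
                          scale=np.sqrt(moments.sum_variance))


def kde_sum_density(series: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) of simulated sum scores on a grid.

    Simulation-based alternative to ``sum_score_density``; near the grid
    boundary the KDE is biased low, so comparisons should be restricted to
    the central region.
    """
    sums = np.asarray(series).sum(axis=1)
    kde = stats.gaussian_kde(sums, bw_method="silverman")
    return kde(np.asarray(grid, dtype=float))
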