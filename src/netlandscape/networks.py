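"""Synthetic baseline networks, grid conditions and connectivity statistics.

The empirical nine-symptom Ising network that motivates the study design is
not publicly available, so baselines are generated synthetically: all-positive
pairwise weights and thresholds drawn around stated condition means, with the
spread calibrated (via the mean-field self-consistency oracle) so that the
connectivity-multiplier sweep {0.9, 1, 2} crosses the mono- to bistable
transition. The GVAR baseline follows the stated sampling distributions:
autoregressive coefficients ~ U(0.2, 0.4), cross-lagged coefficients
~ U(0.1, 0.2), all positive, with a positive partial-correlation
contemporaneous network.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .params import Encoding, GVARParameters, IsingParameters, spectral_radius


class ModelKind(str, enum.Enum):
    ISING_01 = "ising01"
    ISING_PM1 = "isingpm1"
    GVAR = "gvar"


class TauTransform(str, enum.Enum):
    """How a grid condition changes Ising thresholds."""

    IDENTITY = "identity"    # keep the baseline thresholds
    SCALE = "scale"          # multiply by a factor (e.g. x2 or x-1)
    RECENTER = "recenter"    # shift so the sample mean equals a target


@dataclass(frozen=True)
class GridCondition:
    """One cell of the simulation grid before the landscape is computed.

    ``multiplier`` scales the weight matrix (Ising) or the temporal matrix
    (GVAR). The threshold/mean condition is either a transform of the baseline
    thresholds (Ising) or a target stationary mean (GVAR); the contemporaneous
    network of the GVAR model is never touched.
    """

    model: ModelKind
    label: str
    multiplier: float
    tau_transform: TauTransform = TauTransform.IDENTITY
    tau_factor: float = 1.0
    target_mean: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        object.__setattr__(self, "model", ModelKind(self.model))
        object.__setattr__(self, "tau_transform", TauTransform(self.tau_transform))


# Default spread of the generated parameters around their condition means,
# per encoding: (weight s.d., threshold s.d.). Calibrated so the multiplier
# sweep brackets the bifurcation; see docs/methods.md.
DEFAULT_ISING_SPREAD: dict[Encoding, tuple[float, float]] = {
    Encoding.ZERO_ONE: (0.1, 0.5),
    Encoding.MINUS_PLUS: (0.03, 0.1),
}

# Default mean pairwise weight of the baseline network, per encoding.
DEFAULT_MEAN_WEIGHT: dict[Encoding, float] = {
    Encoding.ZERO_ONE: 0.5,
    Encoding.MINUS_PLUS: 0.14,
}


def gen_ising_baseline(
    n_nodes: int,
    encoding: Encoding | str,
    mean_tau: float,
    mean_weight: float | None = None,
    heterogeneity: float = 1.0,
    seed: int = 0,
    *,
    weight_sd: float | None = None,
    tau_sd: float | None = None,
) -> IsingParameters:
    """Generate a baseline Ising network with all-positive weights.

    Weights are drawn from a normal distribution truncated to (0, inf) with
    the given mean; thresholds from a normal around ``mean_tau``. The spread
    defaults depend on the encoding (see ``DEFAULT_ISING_SPREAD``) and are
    scaled by ``heterogeneity``; ``heterogeneity=0`` returns the degenerate
    network with every threshold equal to ``mean_tau`` and every weight equal
    to ``mean_weight``.
    """
    encoding = Encoding(encoding)
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes for a network")
    if mean_weight is None:
        mean_weight = DEFAULT_MEAN_WEIGHT[encoding]
    if mean_weight <= 0:
        raise ValueError("mean_weight must be positive (positive-connection networks)")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be nonnegative")
    w_sd, t_sd = DEFAULT_ISING_SPREAD[encoding]
    w_sd = heterogeneity * (w_sd if weight_sd is None else weight_sd)
    t_sd = heterogeneity * (t_sd if tau_sd is None else tau_sd)

    rng = np.random.default_rng(seed)
    n_pairs = n_nodes * (n_nodes - 1) // 2
    if w_sd > 0:
        a = (0.0 - mean_weight) / w_sd  # truncate at zero: weights stay positive
        w = stats.truncnorm.rvs(a, np.inf, loc=mean_weight, scale=w_sd,
                                size=n_pairs, random_state=rng)
    else:
        w = np.full(n_pairs, mean_weight)
    tau = rng.normal(mean_tau, t_sd, size=n_nodes) if t_sd > 0 else np.full(n_nodes, mean_tau)

    omega = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    omega[iu] = w
    omega += omega.T
    meta = {"seed": seed, "mean_tau": mean_tau, "mean_weight": mean_weight,
            "heterogeneity": heterogeneity, "weight_sd": w_sd, "tau_sd": t_sd}
    return IsingParameters(encoding=encoding, tau=tau, omega=omega, meta=meta)


def _contemporaneous_sigma(
    n_vars: int,
    rng: np.random.Generator,
    partial_corr: float = 0.25,
    rewire_p: float = 0.1,
) -> np.ndarray:
    """Innovation covariance from a small-world positive partial-correlation graph.

    A ring lattice (each node tied to its two nearest neighbours) is rewired
    with probability ``rewire_p``; edges carry equal positive partial
    correlations. The precision matrix (unit diagonal, -rho on edges) is
    inverted and rescaled to unit innovation variances. If rewiring makes the
    precision matrix indefinite the partial correlations are shrunk.
    """
    g = nx.watts_strogatz_graph(n_vars, 2, rewire_p, seed=int(rng.integers(2**31)))
    theta = np.eye(n_vars)
    for i, j in g.edges():
        theta[i, j] = theta[j, i] = -partial_corr
    while np.linalg.eigvalsh(theta).min() < 1e-3:
        theta = np.eye(n_vars) + 0.8 * (theta - np.eye(n_vars))
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def gen_gvar_baseline(
    n_vars: int,
    seed: int = 0,
    *,
    n_cross_edges: int = 2,
    max_multiplier: float = 1.2,
    target_radius: float = 0.95,
) -> GVARParameters:
    """Generate a baseline GVAR network with nonnegative temporal weights.

    Autoregressive (diagonal) coefficients ~ U(0.2, 0.4); each node sends
    ``n_cross_edges`` cross-lagged edges ~ U(0.1, 0.2) to random targets.
    A dense matrix in these ranges would be nonstationary, so the temporal
    network is sparse; if the spectral radius at the largest grid multiplier
    still exceeds ``target_radius`` the whole matrix is rescaled uniformly
    (the scale factor is recorded in ``meta``).
    """
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    rng = np.random.default_rng(seed)
    beta = np.diag(rng.uniform(0.2, 0.4, size=n_vars))
    for j in range(n_vars):
        others = np.delete(np.arange(n_vars), j)
        targets = rng.choice(others, size=min(n_cross_edges, n_vars - 1), replace=False)
        beta[targets, j] = rng.uniform(0.1, 0.2, size=targets.size)

    scale = 1.0
    rho = spectral_radius(max_multiplier * beta)
    if rho > target_radius:
        scale = target_radius / rho
        beta = beta * scale
        rho = spectral_radius(max_multiplier * beta)
    if rho >= 1.0:  # pragma: no cover - rescaling above makes this unreachable
        raise RuntimeError("could not achieve stationarity at the largest multiplier")

    sigma = _contemporaneous_sigma(n_vars, rng)
    meta = {"seed": seed, "n_cross_edges": n_cross_edges,
            "stationarity_rescale": scale, "max_multiplier": max_multiplier}
    return GVARParameters(mu=np.zeros(n_vars), beta=beta, sigma=sigma, meta=meta)


def apply_condition(
    params: IsingParameters | GVARParameters, condition: GridCondition
) -> IsingParameters | GVARParameters:
    """Apply a grid condition (multiplier + threshold/mean change) to a baseline."""
    if isinstance(params, IsingParameters):
        if condition.model is ModelKind.GVAR:
            raise TypeError("GVAR condition applied to Ising parameters")
        tau = params.tau
        tr = condition.tau_transform
        if tr is TauTransform.SCALE:
            tau = tau * condition.tau_factor
        elif tr is TauTransform.RECENTER:
            if condition.target_mean is None:
                raise ValueError("RECENTER condition needs a target_mean")
            tau = tau - tau.mean() + condition.target_mean
        meta = dict(params.meta)
        meta["condition"] = condition.label
        meta["multiplier"] = condition.multiplier
        return params.replace(tau=tau, omega=params.omega * condition.multiplier,
                              meta=meta)
    if isinstance(params, GVARParameters):
        if condition.model is not ModelKind.GVAR:
            raise TypeError("Ising condition applied to GVAR parameters")
        if condition.target_mean is None:
            raise ValueError("GVAR condition needs a target mean mu")
        meta = dict(params.meta)
        meta["condition"] = condition.label
        meta["multiplier"] = condition.multiplier
        return params.replace(mu=np.full(params.n_vars, float(condition.target_mean)),
                              beta=params.beta * condition.multiplier, meta=meta)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def ising_connectivity(omega: np.ndarray) -> float:
    """Weighted average absolute edge strength, 2/(n(n-1)) * sum_{i<j} |w_ij|."""
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("omega must be square")
    n = omega.shape[0]
    if n < 2:
        raise ValueError("connectivity undefined for fewer than 2 nodes")
    if not np.allclose(omega, omega.T, atol=1e-12):
        raise ValueError("omega must be symmetric")
    iu = np.triu_indices(n, k=1)
    return float(2.0 / (n * (n - 1)) * np.sum(np.abs(omega[iu])))


def gvar_connectivity(beta: np.ndarray) -> float:
    """Mean absolute temporal coefficient, (1/n^2) * sum_ij |beta_ij|."""
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 2 or beta.shape[0] != beta.shape[1]:
        raise ValueError("beta must be square")
    return float(np.mean(np.abs(beta)))
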