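"""Exact Ising-model probability computations under both node encodings.

The Ising model assigns a configuration ``x`` (entries in {0,1} or {-1,1})
the probability

    P(X = x) = exp( sum_i tau_i x_i + sum_{i<j} omega_ij x_i x_j ) / Z,

with ``Z`` the sum of the numerator over all 2^n configurations. For the
nine-node networks used here (512 states) the distribution is enumerated
exactly; a seeded single-site heat-bath (Glauber) sampler is provided as an
independent stochastic cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .params import Encoding, IsingParameters

#: Hard cap on exact enumeration; 2^n states must fit comfortably in memory.
ENUMERATION_CAP = 20


@dataclass(frozen=True)
class ConfigurationDistribution:
    """Exact probability of every configuration of an Ising model.

    ``states`` enumerates all 2^n configurations in binary counting order
    with node 0 as the least-significant position (row ``i`` is the bit
    pattern of ``i``, mapped to the encoding's alphabet); that ordering is
    part of the contract so state indices are stable across runs.
    """

    encoding: Encoding
    states: np.ndarray        # (2^n, n) int8, entries in the alphabet
    probabilities: np.ndarray  # (2^n,) nonnegative, sums to 1
    log_z: float = 0.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size != self.states.shape[0]:
            raise ValueError("probabilities must match the number of states")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class ActiveCountDistribution:
    """Distribution of K = number of nodes in state +1 (the "active" state)."""

    probabilities: np.ndarray  # length n+1, index k = P(K = k)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def n_nodes(self) -> int:
        return self.probabilities.size - 1

    @property
    def counts(self) -> np.ndarray:
        return np.arange(self.probabilities.size)


def _check_alphabet(config: np.ndarray, encoding: Encoding) -> np.ndarray:
    config = np.asarray(config)
    if not np.isin(config, encoding.alphabet).all():
        raise ValueError(
            f"configuration entries must be in {encoding.alphabet} for "
            f"encoding {encoding.value!r}")
    return config.astype(float)


def log_weight(config: np.ndarray, params: IsingParameters) -> float:
    """Unnormalised log probability: sum_i tau_i x_i + sum_{i<j} w_ij x_i x_j."""
    x = _check_alphabet(config, params.encoding)
    if x.shape != (params.n_nodes,):
        raise ValueError("configuration length must match the number of nodes")
    # diagonal of omega is zero, so x' W x double-counts each unordered pair
    return float(params.tau @ x + 0.5 * x @ params.omega @ x)


def enumerate_states(n: int, encoding: Encoding) -> np.ndarray:
    """All 2^n configurations in binary counting order (node 0 = LSB)."""
    idx = np.arange(2**n, dtype=np.uint32)
    bits = (idx[:, None] >> np.arange(n, dtype=np.uint32)) & 1
    states = bits.astype(np.int8)
    if encoding is Encoding.MINUS_PLUS:
        states = (2 * states - 1).astype(np.int8)
    return states


def exact_distribution(params: IsingParameters) -> ConfigurationDistribution:
    """Enumerate all configurations and normalise with a max-shifted log-sum-exp."""
    n = params.n_nodes
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"exact enumeration limited to {ENUMERATION_CAP} nodes, got {n}")
    states = enumerate_states(n, params.encoding)
    x = states.astype(float)
    logw = x @ params.tau + 0.5 * np.einsum("si,ij,sj->s", x, params.omega, x)
    log_z = float(logsumexp(logw))
    p = np.exp(logw - log_z)
    p = p / p.sum()  # absorb residual rounding so the sum-to-1 invariant is exact
    return ConfigurationDistribution(encoding=params.encoding, states=states,
                                     probabilities=p, log_z=log_z)


def active_count_distribution(dist: ConfigurationDistribution) -> ActiveCountDistribution:
    """Aggregate configuration probabilities by the number of +1 nodes."""
    k = (dist.states == 1).sum(axis=1)
    n = dist.n_nodes
    p = np.bincount(k, weights=dist.probabilities, minlength=n + 1)
    return ActiveCountDistribution(probabilities=p / p.sum(),
                                   meta={"encoding": dist.encoding.value})


def convert_encoding(params: IsingParameters) -> IsingParameters:
    """Reparameterise to the other encoding, preserving the distribution.

    Substituting x = (s+1)/2 maps {0,1} parameters (tau, omega) to {-1,1}
    parameters omega' = omega/4 and tau'_i = tau_i/2 + sum_{j!=i} omega_ij/4
    (up to an additive constant absorbed by normalisation); the inverse map
    recovers the original. After relabeling 0 <-> -1 the two distributions
    over configurations are identical.
    """
    if params.encoding is Encoding.ZERO_ONE:
        omega_p = params.omega / 4.0
        tau_p = params.tau / 2.0 + params.omega.sum(axis=1) / 4.0
        return params.replace(encoding=Encoding.MINUS_PLUS, tau=tau_p, omega=omega_p)
    omega_p = params.omega * 4.0
    tau_p = 2.0 * (params.tau - params.omega.sum(axis=1))
    return params.replace(encoding=Encoding.ZERO_ONE, tau=tau_p, omega=omega_p)


def active_count_to_sum_score(k: np.ndarray | int, n: int) -> np.ndarray | int:
    """Relabel the active-count axis to the {-1,1} sum score, s = 2k - n."""
    return 2 * np.asarray(k) - n if np.ndim(k) else 2 * k - n


def glauber_counts(
    params: IsingParameters,
    n_samples: int,
    burn_in: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Active-count stream from a single-site heat-bath (Glauber) chain.

    One recorded sample per full sweep of sequential site updates. The
    conditional probability of a node being "on" given the rest is
    ``sigmoid(tau_i + sum_j w_ij x_j)`` for {0,1} nodes and
    ``sigmoid(2 * (tau_i + sum_j w_ij s_j))`` for {-1,1} nodes.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    n = params.n_nodes
    tau, omega = params.tau, params.omega
    pm1 = params.encoding is Encoding.MINUS_PLUS
    lo = -1.0 if pm1 else 0.0
    x = np.where(rng.random(n) < 0.5, 1.0, lo)

    total = burn_in + n_samples
    u = rng.random((total, n))
    out = np.empty(n_samples, dtype=np.int64)
    for t in range(total):
        ut = u[t]
        for i in range(n):
            h = tau[i] + omega[i] @ x
            if pm1:
                h *= 2.0
            p_on = 1.0 / (1.0 + np.exp(-h))
            x[i] = 1.0 if ut[i] < p_on else lo
        if t >= burn_in:
            out[t - burn_in] = int(np.count_nonzero(x == 1.0))
    return out


def glauber_sample(
    params: IsingParameters,
    n_samples: int,
    burn_in: int = 1000,
    seed: int = 0,
) -> ActiveCountDistribution:
    """Empirical active-count distribution from the Glauber chain."""
    k = glauber_counts(params, n_samples, burn_in=burn_in, seed=seed)
    p = np.bincount(k, minlength=params.n_nodes + 1).astype(float)
    return ActiveCountDistribution(
        probabilities=p / p.sum(),
        meta={"sampler": "glauber", "n_samples": n_samples,
              "burn_in": burn_in, "seed": seed})
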