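"""Parameter containers for the two idiographic network models.

An Ising network is described by per-node thresholds ``tau`` and a symmetric
zero-diagonal weight matrix ``omega``; the node alphabet ({0,1} or {-1,1})
changes the meaning of the weights, so the encoding is part of the parameters.
A graphical VAR (GVAR) process is described by stationary means ``mu``, a
lag-1 temporal matrix ``beta`` (rows are effect targets) and an innovation
covariance ``sigma`` encoding the contemporaneous network.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np


class Encoding(str, enum.Enum):
    """Node alphabet of the Ising model."""

    ZERO_ONE = "01"
    MINUS_PLUS = "pm1"

    @property
    def alphabet(self) -> tuple[int, int]:
        return (0, 1) if self is Encoding.ZERO_ONE else (-1, 1)


def _as_vector(x: Any, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite")
    return v


def _as_square(x: Any, n: int, name: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError(f"{name} must be finite")
    return m


@dataclass(frozen=True)
class IsingParameters:
    """Thresholds and pairwise weights of an Ising network.

    Parameters
    ----------
    encoding
        Node alphabet, ``Encoding.ZERO_ONE`` or ``Encoding.MINUS_PLUS``.
    tau
        Length-``n`` vector of thresholds (autonomous activation tendency;
        negative values favour the "off" state).
    omega
        Symmetric ``n x n`` weight matrix with an exactly zero diagonal.
    """

    encoding: Encoding
    tau: np.ndarray
    omega: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        tau = _as_vector(self.tau, "tau")
        n = tau.size
        if n < 1:
            raise ValueError("need at least one node")
        omega = _as_square(self.omega, n, "omega")
        if not np.allclose(omega, omega.T, atol=1e-12):
            raise ValueError("omega must be symmetric")
        if np.any(np.diag(omega) != 0.0):
            raise ValueError("omega must have an exactly zero diagonal")
        object.__setattr__(self, "encoding", Encoding(self.encoding))
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "omega", omega)

    @property
    def n_nodes(self) -> int:
        return self.tau.size

    def replace(self, **kw: Any) -> "IsingParameters":
        d = {"encoding": self.encoding, "tau": self.tau, "omega": self.omega,
             "meta": dict(self.meta)}
        d.update(kw)
        return IsingParameters(**d)

    def to_dict(self) -> dict:
        return {
            "model": "ising",
            "encoding": self.encoding.value,
            "tau": self.tau.tolist(),
            "omega": self.omega.tolist(),
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IsingParameters":
        if d.get("model") != "ising":
            raise ValueError(f"expected model 'ising', got {d.get('model')!r}")
        return cls(encoding=Encoding(d["encoding"]), tau=np.asarray(d["tau"]),
                   omega=np.asarray(d["omega"]), meta=d.get("meta", {}))


@dataclass(frozen=True)
class GVARParameters:
    """Means, temporal matrix and innovation covariance of a GVAR process.

    The process is ``y_t = mu + beta @ (y_{t-1} - mu) + eps_t`` with
    ``eps_t ~ N(0, sigma)``. Stationarity (spectral radius of ``beta`` < 1)
    and positive-definiteness of ``sigma`` are enforced at construction.
    """

    mu: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        mu = _as_vector(self.mu, "mu")
        n = mu.size
        if n < 1:
            raise ValueError("need at least one variable")
        beta = _as_square(self.beta, n, "beta")
        sigma = _as_square(self.sigma, n, "sigma")
        rho = spectral_radius(beta)
        if rho >= 1.0:
            raise ValueError(
                f"temporal matrix is nonstationary: spectral radius {rho:.4f} >= 1")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise ValueError("sigma must be positive definite")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n_vars(self) -> int:
        return self.mu.size

    def replace(self, **kw: Any) -> "GVARParameters":
        d = {"mu": self.mu, "beta": self.beta, "sigma": self.sigma,
             "meta": dict(self.meta)}
        d.update(kw)
        return GVARParameters(**d)

    def to_dict(self) -> dict:
        return {
            "model": "gvar",
            "mu": self.mu.tolist(),
            "beta": self.beta.tolist(),
            "sigma": self.sigma.tolist(),
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GVARParameters":
        if d.get("model") != "gvar":
            raise ValueError(f"expected model 'gvar', got {d.get('model')!r}")
        return cls(mu=np.asarray(d["mu"]), beta=np.asarray(d["beta"]),
                   sigma=np.asarray(d["sigma"]), meta=d.get("meta", {}))


NetworkParameters = IsingParameters | GVARParameters


def spectral_radius(m: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(m, dtype=float)))))


def save_network(params: NetworkParameters, path: str | Path) -> None:
    """Write parameters to the network JSON schema (row-major full matrices)."""
    Path(path).write_text(json.dumps(params.to_dict(), indent=1))


def load_network(path: str | Path) -> NetworkParameters:
    """Read parameters from the network JSON schema."""
    d = json.loads(Path(path).read_text())
    if d.get("model") == "ising":
        return IsingParameters.from_dict(d)
    if d.get("model") == "gvar":
        return GVARParameters.from_dict(d)
    raise ValueError(f"unknown model kind {d.get('model')!r}")
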