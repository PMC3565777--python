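"""Gaussian-mixture stationary density, potential landscape and drift.

The population of reporter levels (on the log10 fluorescence scale) is modelled
as the stationary density of a one-dimensional stochastic dynamical system

    dX = A(X) dt + sqrt(2B) dW,

whose stationary law ``p_s`` is represented non-parametrically as a mixture of
``k`` Gaussians.  With a constant diffusion coefficient ``2B`` the zero
probability-current condition gives the potential ``U(x) = -B log p_s(x)`` and
the drift ``A(x) = -U'(x) = B d/dx log p_s(x)``.  The drift is evaluated
analytically (a responsibility-weighted sum of Gaussian score functions), never
by finite differences, because the likelihood calls it millions of times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MixtureParams",
    "StochasticModel",
    "mixture_density",
    "log_mixture_density",
    "potential",
    "drift",
    "sample_stationary",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MixtureParams:
    """Weights, means and variances of the k-component stationary mixture.

    Components are canonicalized to strictly ascending means at construction
    (weights and variances are permuted along), which removes the
    label-switching ambiguity of mixture parameterizations.  Weights whose sum
    is within 1e-6 of one are renormalized exactly; anything further off is
    rejected.
    """

    weights: tuple[float, ...]
    means: tuple[float, ...]
    variances: tuple[float, ...]

    def __init__(
        self,
        weights: Sequence[float],
        means: Sequence[float],
        variances: Sequence[float],
    ) -> None:
        w = np.asarray(weights, dtype=float)
        m = np.asarray(means, dtype=float)
        v = np.asarray(variances, dtype=float)
        if not (w.ndim == m.ndim == v.ndim == 1) or not (len(w) == len(m) == len(v)):
            raise ValueError("weights, means and variances must be 1-D and of equal length")
        if len(w) < 1:
            raise ValueError("at least one mixture component is required")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(m)) and np.all(np.isfinite(v))):
            raise ValueError("mixture parameters must be finite")
        if np.any(w <= 0.0) or np.any(w >= 1.0 + 1e-12):
            if len(w) > 1 or not np.isclose(w[0], 1.0, atol=1e-6):
                raise ValueError("weights must lie in (0, 1)")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.8f})")
        w = w / w.sum()
        if np.any(v <= 0.0):
            raise ValueError("variances must be positive")
        order = np.argsort(m, kind="stable")
        m, w, v = m[order], w[order], v[order]
        if len(m) > 1 and np.any(np.diff(m) <= 0.0):
            raise ValueError("component means must be distinct")
        object.__setattr__(self, "weights", tuple(w.tolist()))
        object.__setattr__(self, "means", tuple(m.tolist()))
        object.__setattr__(self, "variances", tuple(v.tolist()))

    @property
    def k(self) -> int:
        return len(self.weights)

    @classmethod
    def from_percentages(
        cls,
        percentages: Sequence[float],
        means: Sequence[float],
        variances: Sequence[float],
    ) -> "MixtureParams":
        """Build from occupancy percentages (renormalized by their own sum)."""
        p = np.asarray(percentages, dtype=float)
        return cls(p / p.sum(), means, variances)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": list(self.weights),
            "means": list(self.means),
            "variances": list(self.variances),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        p = cls(d["weights"], d["means"], d["variances"])
        if "k" in d and int(d["k"]) != p.k:
            raise ValueError("declared k does not match parameter length")
        return p


@dataclass(frozen=True)
class StochasticModel:
    """A mixture stationary law plus a constant noise intensity B.

    ``B`` has units (log10 fluorescence)^2 / day; the induced potential is
    ``U(x) = -B log p_s(x)`` and the drift ``A(x) = -U'(x)``.
    """

    mixture: MixtureParams
    noise: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.noise) or self.noise <= 0.0:
            raise ValueError("noise intensity B must be positive and finite")

    def potential(self, x) -> np.ndarray | float:
        return potential(self, x)

    def drift(self, x) -> np.ndarray | float:
        return drift(self, x)

    def to_json(self) -> str:
        d = self.mixture.to_dict()
        d["noise"] = self.noise
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "StochasticModel":
        d = json.loads(s)
        return cls(MixtureParams.from_dict(d), float(d["noise"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "StochasticModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _check_x(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    return arr


def _component_logpdfs(params: MixtureParams, x: np.ndarray) -> np.ndarray:
    """log(alpha_i) + log Normal(x; mu_i, var_i), shape (..., k)."""
    m = np.asarray(params.means)
    v = np.asarray(params.variances)
    lw = np.log(np.asarray(params.weights))
    z2 = (x[..., None] - m) ** 2 / v
    return lw - 0.5 * (z2 + np.log(v) + _LOG_2PI)


def log_mixture_density(params: MixtureParams, x) -> np.ndarray | float:
    """Numerically stable log of the stationary mixture density.

    Computed by log-sum-exp over components, so it does not overflow or
    underflow even far into the tails (|x| up to ~50 is routine).
    """
    arr = _check_x(x)
    out = logsumexp(_component_logpdfs(params, arr), axis=-1)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def mixture_density(params: MixtureParams, x) -> np.ndarray | float:
    """Stationary mixture density p_s(x), per log10 unit."""
    return np.exp(log_mixture_density(params, x))


def potential(model: StochasticModel, x) -> np.ndarray | float:
    """Potential landscape U(x) = -B log p_s(x).

    Minima of U coincide with maxima of p_s; scaling B scales U pointwise and
    leaves the stationary density untouched.
    """
    return -model.noise * log_mixture_density(model.mixture, x)


def drift(model: StochasticModel, x) -> np.ndarray | float:
    """Drift A(x) = -U'(x) = B * d/dx log p_s(x), analytically.

    The score of a Gaussian mixture is the responsibility-weighted average of
    the component scores (mu_i - x)/var_i; responsibilities are computed in log
    space so the tails are exact (where the drift tends to the dominant
    component's linear mean reversion).
    """
    arr = _check_x(x)
    params = model.mixture
    logp = _component_logpdfs(params, arr)
    resp = np.exp(logp - logsumexp(logp, axis=-1, keepdims=True))
    score = (np.asarray(params.means) - arr[..., None]) / np.asarray(params.variances)
    out = model.noise * np.sum(resp * score, axis=-1)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def sample_stationary(params: MixtureParams, n: int, seed=None) -> np.ndarray:
    """Exact ancestral draws from the stationary mixture.

    A component index is drawn with probability alpha_i, then a Gaussian draw
    from that component.  ``seed`` may be an int or a numpy Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = rng.choice(params.k, size=n, p=np.asarray(params.weights))
    m = np.asarray(params.means)[comp]
    s = np.sqrt(np.asarray(params.variances))[comp]
    return m + s * rng.standard_normal(n)
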