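"""Euler-Maruyama simulation of reporter-level trajectories.

The stochastic system is dX = A(X) dt + sqrt(2B) dW with the analytic
mixture-score drift.  The integrator is plain Euler-Maruyama: the drift is
mean-reverting in both tails (asymptotically linear towards the nearest
component mean), so trajectories are self-confining and no boundary handling
is needed.  Each simulate() call owns one counter-based Philox generator
seeded explicitly, so ensembles are bit-reproducible for a fixed
(seed, dt, n) and independent of global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import em_segment
from .mixture import StochasticModel

__all__ = ["TrajectoryEnsemble", "simulate", "endpoint_density"]

# cap per-segment normal blocks at ~10M draws to bound memory on big ensembles
_MAX_BLOCK = 10_000_000


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Simulated ensemble positions on a recording time grid.

    positions has shape (n_traj, n_times); column 0 is the supplied initial
    states and column j the state at times[j] (times snapped to the step
    grid).
    """

    times: np.ndarray
    positions: np.ndarray
    seed: int
    dt: float

    @property
    def n_traj(self) -> int:
        return self.positions.shape[0]

    def at(self, time_index: int) -> np.ndarray:
        return self.positions[:, time_index]

    def to_csv(self, path_or_buf) -> None:
        """One row per trajectory, one column per recorded time."""
        header = ",".join(repr(float(t)) for t in self.times)
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            with open(path_or_buf, "w") as fh:
                np.savetxt(fh, self.positions, delimiter=",", header=header, comments="")
        else:
            np.savetxt(path_or_buf, self.positions, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path, seed: int = -1, dt: float = np.nan) -> "TrajectoryEnsemble":
        with open(path) as fh:
            times = np.array([float(v) for v in fh.readline().strip().split(",")])
            positions = np.loadtxt(fh, delimiter=",", ndmin=2)
        return cls(times=times, positions=positions, seed=seed, dt=dt)


def _snap_steps(record_times: np.ndarray, dt: float) -> np.ndarray:
    return np.rint(np.asarray(record_times, dtype=float) / dt).astype(np.int64)


def simulate(
    model: StochasticModel,
    initial_states,
    record_times,
    dt: float = 0.01,
    seed: int | None = None,
    drift_fn=None,
) -> TrajectoryEnsemble:
    """Simulate an ensemble and record it at the requested times.

    record_times must be strictly increasing and start at 0; each is snapped
    to the nearest integer multiple of dt.  ``drift_fn`` overrides the model
    drift (a test hook, e.g. zero drift for pure diffusion); the override path
    runs in numpy rather than the compiled kernel.
    """
    x0 = np.ascontiguousarray(initial_states, dtype=float).ravel()
    if x0.size == 0:
        raise ValueError("initial_states must be non-empty")
    times = np.asarray(record_times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("record_times must be a non-empty 1-D sequence")
    if times[0] != 0.0:
        raise ValueError("record_times must start at 0")
    if np.any(np.diff(times) <= 0.0):
        raise ValueError("record_times must be strictly increasing")
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if times.size > 1 and dt > np.min(np.diff(times)) + 1e-12:
        raise ValueError("dt must not exceed the smallest record-time gap")

    steps = _snap_steps(times, dt)
    seed = 0 if seed is None else int(seed)
    rng = np.random.Generator(np.random.Philox(seed))

    n = x0.size
    positions = np.empty((n, times.size), dtype=float)
    positions[:, 0] = x0
    x = x0.copy()

    logw = np.log(np.asarray(model.mixture.weights))
    means = np.asarray(model.mixture.means)
    variances = np.asarray(model.mixture.variances)
    sigma_dt = np.sqrt(2.0 * model.noise * dt)

    for j in range(1, times.size):
        n_steps = int(steps[j] - steps[j - 1])
        done = 0
        while done < n_steps:
            block = min(n_steps - done, max(1, _MAX_BLOCK // n))
            normals = rng.standard_normal((block, n))
            if drift_fn is None:
                em_segment(x, normals, dt, sigma_dt, logw, means, variances, model.noise)
            else:
                for s in range(block):
                    x += drift_fn(x) * dt + sigma_dt * normals[s]
            done += block
        positions[:, j] = x
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("trajectory diverged; reduce dt")

    return TrajectoryEnsemble(times=times.copy(), positions=positions, seed=seed, dt=float(dt))


def endpoint_density(ensemble: TrajectoryEnsemble, time_index: int):
    """Gaussian KDE of the ensemble marginal at one recorded time.

    Silverman bandwidth; evaluation far outside the support returns the
    configured log-density floor, never zero.
    """
    from .kde import GaussianKDE1D

    values = ensemble.at(time_index)
    return GaussianKDE1D(values)
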