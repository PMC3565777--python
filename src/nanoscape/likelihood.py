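"""Snapshot time-course and stationary likelihoods.

The time-course likelihood treats each measurement day after day 0 as an
independent snapshot (samples are destructive: fresh cells are analysed each
day), all conditioned on the day-0 population.  The day-0 sample defines a
kernel density estimate; trajectories started from that estimate are pushed
forward with the stochastic integrator and the density at each later day is
approximated by a KDE of the simulated ensemble.  With a fixed seed the value
is deterministic, which is what a nested sampler needs from a simulation-based
likelihood (common random numbers across parameter vectors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import mixture_logpdf_sum
from .kde import GaussianKDE1D
from .mixture import MixtureParams, StochasticModel
from .sde import simulate

__all__ = ["TimeCourseDataset", "TimecourseLikelihood", "loglik_timecourse", "loglik_stationary"]


@dataclass(frozen=True)
class TimeCourseDataset:
    """Per-day sets of log10 fluorescence values for one culture condition."""

    condition: str
    times: tuple[float, ...]
    samples: tuple[np.ndarray, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if len(times) < 1 or times[0] != 0.0:
            raise ValueError("times must start at t_0 = 0")
        if np.any(np.diff(times) <= 0.0):
            raise ValueError("times must be strictly increasing")
        if len(self.samples) != len(times):
            raise ValueError("one sample set per time point is required")
        samples = tuple(np.asarray(s, dtype=float).ravel() for s in self.samples)
        for s in samples:
            if s.size < 1:
                raise ValueError("every time point needs at least one value")
            if not np.all(np.isfinite(s)):
                raise ValueError("samples must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "samples", samples)

    @property
    def n_per_day(self) -> tuple[int, ...]:
        return tuple(s.size for s in self.samples)

    # -- tidy CSV dialect: condition, day, log10_value ---------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame(
                {"condition": self.condition, "day": t, "log10_value": s}
            )
            for t, s in zip(self.times, self.samples)
        ]
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str | None = None) -> "TimeCourseDataset":
        if condition is None:
            conditions = df["condition"].unique()
            if len(conditions) != 1:
                raise ValueError("frame holds several conditions; pass one explicitly")
            condition = str(conditions[0])
        sub = df[df["condition"] == condition]
        times = sorted(sub["day"].unique())
        samples = tuple(
            sub.loc[sub["day"] == t, "log10_value"].to_numpy(dtype=float) for t in times
        )
        return cls(condition=condition, times=tuple(float(t) for t in times), samples=samples)

    @classmethod
    def from_csv(cls, path, condition: str | None = None) -> "TimeCourseDataset":
        return cls.from_frame(pd.read_csv(path), condition=condition)


def loglik_stationary(params: MixtureParams, values) -> float:
    """Sum of log stationary-mixture densities of iid values.

    This scores a snapshot of an equilibrated population under the stationary
    law alone; it is independent of the noise intensity B, which is exactly
    why stationary data cannot identify the potential/noise split.
    """
    arr = np.ascontiguousarray(values, dtype=float).ravel()
    if arr.size == 0:
        return 0.0
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return float(
        mixture_logpdf_sum(
            arr,
            np.log(np.asarray(params.weights)),
            np.asarray(params.means),
            np.asarray(params.variances),
        )
    )


class TimecourseLikelihood:
    """Seed-frozen simulation likelihood with precomputed random numbers.

    For a fixed seed, ``loglik_timecourse`` draws the same initial states and
    the same Brownian increments on every call; this evaluator draws them
    once and reuses them for every parameter vector (common random numbers),
    reproducing loglik_timecourse(model, data, n_traj, dt, seed) bit for bit
    at a fraction of the cost.  This is the likelihood a nested-sampling run
    sees: deterministic, noisy-but-fixed.
    """

    def __init__(self, data: TimeCourseDataset, n_traj: int = 1000,
                 dt: float = 0.01, seed: int = 0):
        if len(data.times) < 2:
            raise ValueError("need at least one post-initial day")
        rng = np.random.Generator(np.random.Philox(int(seed)))
        kde0 = GaussianKDE1D(data.samples[0])
        self.x0 = kde0.resample(int(n_traj), rng)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        self.times = np.asarray(data.times, dtype=float)
        steps = np.rint(self.times / dt).astype(np.int64)
        seg_steps = np.diff(steps)
        # same Philox stream and block layout as sde.simulate
        rng_sim = np.random.Generator(np.random.Philox(sim_seed))
        self.normals = [rng_sim.standard_normal((int(s), int(n_traj))) for s in seg_steps]
        self.obs = [np.ascontiguousarray(s, dtype=float) for s in data.samples[1:]]
        self.dt = float(dt)
        # a diverged ensemble scores every observed cell at the KDE log floor:
        # the region of parameter space is (correctly) astronomically
        # disfavoured, and the sampler keeps a finite surface
        self.divergence_floor = -700.0 * sum(o.size for o in self.obs)

    def __call__(self, model: StochasticModel) -> float:
        logw = np.log(np.asarray(model.mixture.weights))
        means = np.asarray(model.mixture.means)
        variances = np.asarray(model.mixture.variances)
        return self.evaluate(logw, means, variances, model.noise)

    def evaluate(self, logw, means, variances, noise) -> float:
        from ._kernels import em_segment

        sigma_dt = np.sqrt(2.0 * noise * self.dt)
        x = self.x0.copy()
        total = 0.0
        for normals, obs in zip(self.normals, self.obs):
            em_segment(x, normals, self.dt, sigma_dt, logw, means, variances, noise)
            if not np.all(np.isfinite(x)):
                return self.divergence_floor
            kde_r = GaussianKDE1D(x)
            total += float(np.sum(kde_r.logpdf(obs)))
        return total


def loglik_timecourse(
    model: StochasticModel,
    data: TimeCourseDataset,
    n_traj: int = 1000,
    dt: float = 0.01,
    seed: int = 0,
) -> float:
    """Simulation-based log likelihood of a snapshot time course.

    Steps: KDE on the day-0 sample; n_traj initial states drawn from that
    KDE (smoothed bootstrap); one ensemble simulated to the last day and
    recorded at every measurement day; per day, a KDE of the ensemble scores
    the observed cells; the per-day log likelihoods are summed.  One ensemble
    is shared across days because every day is conditioned on the same day-0
    law, and the reuse cuts both cost and Monte-Carlo variance.
    """
    if len(data.times) < 2:
        warnings.warn("dataset has no post-initial days; likelihood is an empty product")
        return 0.0
    rng = np.random.Generator(np.random.Philox(int(seed)))
    kde0 = GaussianKDE1D(data.samples[0])
    x0 = kde0.resample(int(n_traj), rng)
    sim_seed = int(rng.integers(0, 2**31 - 1))
    try:
        ens = simulate(model, x0, data.times, dt=dt, seed=sim_seed)
    except FloatingPointError:
        # stiff parameter corners (B/var >> 1/dt) blow up the integrator;
        # score every observed cell at the KDE log floor, matching
        # TimecourseLikelihood.evaluate
        return -700.0 * sum(s.size for s in data.samples[1:])
    total = 0.0
    for r in range(1, len(data.times)):
        kde_r = GaussianKDE1D(ens.at(r))
        total += float(np.sum(kde_r.logpdf(data.samples[r])))
    return total
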