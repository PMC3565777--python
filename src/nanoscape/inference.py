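"""Model fitting, evidence-based model comparison and posterior contrasts.

Fitting a time course yields a joint posterior over the mixture parameters and
the noise intensity B; fitting a stationary snapshot yields a posterior over
the mixture alone (B drops out of the stationary law up to a rescaling of the
potential, so it is not identifiable there).  Evidences from separate runs
with different component counts k are compared with Bayes factors; posteriors
from different culture conditions are compared parameter-wise with
P(theta_A < theta_B).
"""

from __future__ import annotations

import numpy as np

from .likelihood import (
    TimecourseLikelihood,
    TimeCourseDataset,
    loglik_stationary,
)
from .mixture import MixtureParams, StochasticModel
from .nested import PosteriorResult, PriorSpec, run_nested_sampling

__all__ = [
    "fit_timecourse",
    "fit_stationary_mixture",
    "bayes_factor",
    "interpret_bayes_factor",
    "posterior_compare",
    "model_from_vector",
    "posterior_mean_model",
]

# odds bands for Bayes-factor magnitudes
BF_BANDS = ((1.0, 3.0, "marginal"), (3.0, 10.0, "substantial"), (10.0, np.inf, "strong"))


def model_from_vector(theta: np.ndarray, k: int, with_noise: bool = True):
    """(alpha_1..k, mu_1..k, var_1..k[, B]) -> StochasticModel or MixtureParams."""
    theta = np.asarray(theta, dtype=float)
    mix = MixtureParams(theta[:k], theta[k: 2 * k], theta[2 * k: 3 * k])
    if with_noise:
        return StochasticModel(mix, float(theta[3 * k]))
    return mix


def posterior_mean_model(result: PosteriorResult, k: int):
    """Posterior-mean parameter vector as a model object."""
    mean = result.posterior_mean()
    theta = np.array([mean[n] for n in result.param_names])
    return model_from_vector(theta, k, with_noise="B" in result.param_names)


def fit_timecourse(
    data: TimeCourseDataset,
    k: int = 3,
    prior: PriorSpec | None = None,
    *,
    n_live: int = 400,
    n_traj: int = 1000,
    dt: float = 0.02,
    walk_steps: int = 25,
    seed: int = 0,
    likelihood_seed: int | None = None,
) -> PosteriorResult:
    """Nested-sampling fit of the dynamic landscape model to a time course.

    The simulation-based likelihood is frozen with one fixed seed for the
    whole run (common random numbers), so the sampler sees a deterministic
    surface.  By default that seed is derived from ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if prior is None:
        prior = PriorSpec(k=k)
    if prior.noise_bounds is None:
        raise ValueError("time-course fits need noise_bounds in the prior")
    if likelihood_seed is None:
        likelihood_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))

    evaluator = TimecourseLikelihood(data, n_traj=n_traj, dt=dt, seed=likelihood_seed)

    def loglik(theta: np.ndarray) -> float:
        return evaluator.evaluate(
            np.log(theta[:k]), theta[k: 2 * k], theta[2 * k: 3 * k], float(theta[3 * k])
        )

    result = run_nested_sampling(
        loglik, prior, n_live=n_live, seed=seed, walk_steps=walk_steps
    )
    result.settings.update(
        {"kind": "timecourse", "k": k, "n_traj": n_traj, "dt": dt,
         "likelihood_seed": likelihood_seed, "condition": data.condition}
    )
    return result


def fit_stationary_mixture(
    values,
    k: int,
    prior: PriorSpec | None = None,
    *,
    n_live: int = 400,
    walk_steps: int = 25,
    seed: int = 0,
) -> PosteriorResult:
    """Nested-sampling fit of the iid stationary mixture (no dynamics, no B)."""
    arr = np.ascontiguousarray(values, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if arr.size < 10 * k:
        raise ValueError(f"need at least {10 * k} values to fit k={k} components")
    if prior is None:
        prior = PriorSpec(k=k, noise_bounds=None)
    elif prior.noise_bounds is not None:
        prior = PriorSpec(k=prior.k, mean_bounds=prior.mean_bounds,
                          sd_bounds=prior.sd_bounds, noise_bounds=None,
                          weight_concentration=prior.weight_concentration)

    def loglik(theta: np.ndarray) -> float:
        mix = model_from_vector(theta, k, with_noise=False)
        return loglik_stationary(mix, arr)

    result = run_nested_sampling(
        loglik, prior, n_live=n_live, seed=seed, walk_steps=walk_steps
    )
    result.settings.update({"kind": "stationary", "k": k, "n_values": int(arr.size)})
    return result


def bayes_factor(result_a: PosteriorResult, result_b: PosteriorResult) -> float:
    """exp(logZ_a - logZ_b): evidence odds of model a over model b."""
    return float(np.exp(result_a.logz - result_b.logz))


def interpret_bayes_factor(bf: float) -> str:
    """Classify the magnitude of a Bayes factor into odds bands.

    Bands on the magnitude max(bf, 1/bf): [1, 3) marginal, [3, 10]
    substantial, above 10 strong.  A factor below one is classified by its
    reciprocal; the direction of the odds is the caller's bookkeeping.
    """
    if bf <= 0 or not np.isfinite(bf):
        raise ValueError("Bayes factor must be positive and finite")
    mag = max(bf, 1.0 / bf)
    if mag > 10.0:
        return "strong"
    if mag >= 3.0:
        return "substantial"
    return "marginal"


def posterior_compare(
    post_a: PosteriorResult,
    post_b: PosteriorResult,
    param_name: str,
    n_pairs: int = 100_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo estimate of P(theta_A < theta_B) for one parameter.

    Independent equal-weight resamples of each posterior are paired; exact
    ties count one half (unbiased for continuous posteriors).
    """
    if param_name not in post_a.param_names or param_name not in post_b.param_names:
        raise ValueError(
            f"parameter {param_name!r} must be present in both posteriors "
            f"({post_a.param_names} vs {post_b.param_names})"
        )
    rng = np.random.default_rng(seed)
    ia = post_a.param_names.index(param_name)
    ib = post_b.param_names.index(param_name)
    a = post_a.resample(n_pairs, rng)[:, ia]
    b = post_b.resample(n_pairs, rng)[:, ib]
    return float(np.mean(a < b) + 0.5 * np.mean(a == b))
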