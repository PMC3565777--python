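"""scikit-learn style estimators wrapping the Bayesian landscape fits.

Both estimators follow the sklearn contract: hyperparameters in __init__,
``fit`` validating its inputs and setting trailing-underscore attributes,
get_params/set_params inherited from BaseEstimator, so they compose with
sklearn model-selection utilities.  The heavy lifting stays in the library
functions (fit_stationary_mixture / fit_timecourse).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils.validation import check_is_fitted

from .inference import fit_stationary_mixture, fit_timecourse, posterior_mean_model
from .likelihood import TimeCourseDataset, loglik_stationary
from .mixture import drift as _drift
from .mixture import log_mixture_density, potential as _potential, sample_stationary
from .nested import PriorSpec

__all__ = ["StationaryMixture", "PotentialLandscape"]


def _column(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("expected a 1-D array or a single-column 2-D array")
    return X


class StationaryMixture(DensityMixin, BaseEstimator):
    """Bayesian Gaussian-mixture density of an equilibrated population.

    Fits the k-component stationary mixture by nested sampling, exposing the
    posterior-mean parameters and the log evidence (for Bayes-factor
    comparison of component counts).

    Parameters
    ----------
    k : number of mixture components.
    n_live, walk_steps : nested-sampling settings.
    prior : optional PriorSpec overriding the default bounds.
    random_state : seed for the sampler.
    """

    def __init__(self, k: int = 3, n_live: int = 400, walk_steps: int = 25,
                 prior: PriorSpec | None = None, random_state: int = 0):
        self.k = k
        self.n_live = n_live
        self.walk_steps = walk_steps
        self.prior = prior
        self.random_state = random_state

    def fit(self, X, y=None):
        x = _column(X)
        self.posterior_ = fit_stationary_mixture(
            x, self.k, self.prior, n_live=self.n_live,
            walk_steps=self.walk_steps, seed=self.random_state,
        )
        self.log_evidence_ = self.posterior_.logz
        self.log_evidence_err_ = self.posterior_.logzerr
        mix = posterior_mean_model(self.posterior_, self.k)
        self.mixture_ = mix
        self.weights_ = np.asarray(mix.weights)
        self.means_ = np.asarray(mix.means)
        self.variances_ = np.asarray(mix.variances)
        self.n_features_in_ = 1
        return self

    def score_samples(self, X) -> np.ndarray:
        check_is_fitted(self, "mixture_")
        return np.atleast_1d(log_mixture_density(self.mixture_, _column(X)))

    def score(self, X, y=None) -> float:
        """Mean log density per sample (sklearn density convention)."""
        return float(np.mean(self.score_samples(X)))

    def sample(self, n_samples: int = 1, random_state=None) -> np.ndarray:
        check_is_fitted(self, "mixture_")
        return sample_stationary(self.mixture_, n_samples, random_state)


class PotentialLandscape(BaseEstimator):
    """Potential landscape plus noise intensity fitted to snapshot dynamics.

    ``fit(X, t)`` takes per-cell log10 values X and their measurement day t
    (day 0 must be present) and runs the nested-sampling fit of the dynamic
    model; the fitted attributes expose the posterior, the evidence and the
    posterior-mean model, from which the potential U(x), the drift A(x) and
    the noise B follow.
    """

    def __init__(self, k: int = 3, n_live: int = 400, n_traj: int = 1000,
                 dt: float = 0.02, walk_steps: int = 25,
                 prior: PriorSpec | None = None, random_state: int = 0,
                 likelihood_seed: int | None = None, condition: str = "fit"):
        self.k = k
        self.n_live = n_live
        self.n_traj = n_traj
        self.dt = dt
        self.walk_steps = walk_steps
        self.prior = prior
        self.random_state = random_state
        self.likelihood_seed = likelihood_seed
        self.condition = condition

    def _dataset(self, X, t) -> TimeCourseDataset:
        x = _column(X)
        t = np.asarray(t, dtype=float).ravel()
        if x.shape != t.shape:
            raise ValueError("X and t must align one measurement day per cell")
        days = np.unique(t)
        samples = tuple(x[t == d] for d in days)
        return TimeCourseDataset(condition=self.condition,
                                 times=tuple(days), samples=samples)

    def fit(self, X, t=None):
        if t is None:
            raise ValueError("fit requires per-cell measurement days t")
        data = X if isinstance(X, TimeCourseDataset) else self._dataset(X, t)
        self.posterior_ = fit_timecourse(
            data, self.k, self.prior, n_live=self.n_live, n_traj=self.n_traj,
            dt=self.dt, walk_steps=self.walk_steps, seed=self.random_state,
            likelihood_seed=self.likelihood_seed,
        )
        self.log_evidence_ = self.posterior_.logz
        self.log_evidence_err_ = self.posterior_.logzerr
        self.model_ = posterior_mean_model(self.posterior_, self.k)
        self.noise_ = self.model_.noise
        self.weights_ = np.asarray(self.model_.mixture.weights)
        self.means_ = np.asarray(self.model_.mixture.means)
        self.variances_ = np.asarray(self.model_.mixture.variances)
        self.n_features_in_ = 1
        return self

    def potential(self, x):
        check_is_fitted(self, "model_")
        return _potential(self.model_, x)

    def drift(self, x):
        check_is_fitted(self, "model_")
        return _drift(self.model_, x)

    def score_stationary(self, X) -> float:
        """Mean predicted stationary log density of held-out snapshot values."""
        check_is_fitted(self, "model_")
        x = _column(X)
        return loglik_stationary(self.model_.mixture, x) / x.size

    def sample_stationary(self, n_samples: int = 1, random_state=None) -> np.ndarray:
        check_is_fitted(self, "model_")
        return sample_stationary(self.model_.mixture, n_samples, random_state)
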