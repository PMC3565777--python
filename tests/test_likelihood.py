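"""Snapshot time-course likelihood and stationary scoring."""

import numpy as np
import pytest

from nanoscape import (
    GaussianKDE1D,
    InitialSpec,
    MixtureParams,
    StochasticModel,
    TimecourseLikelihood,
    TimeCourseDataset,
    generate_timecourse,
    loglik_stationary,
    loglik_timecourse,
    sample_stationary,
)

from oracles import evolve_density_cn, ou_day_logpdf


@pytest.fixture(scope="module")
def ou_dataset(ou_model):
    init = InitialSpec("sorted_fraction", center=0.8, width=0.1)
    return generate_timecourse(ou_model, init, [0, 1, 2], 600, dt=0.005, seed=21)


class TestStationaryLoglik:
    def test_single_value_at_mode(self, std_normal_mixture):
        assert loglik_stationary(std_normal_mixture, [0.0]) == pytest.approx(
            -0.918939, abs=1e-6
        )

    def test_permutation_invariant(self, symmetric_bimodal):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 50)
        a = loglik_stationary(symmetric_bimodal, values)
        b = loglik_stationary(symmetric_bimodal, rng.permutation(values))
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_values_give_zero(self, std_normal_mixture):
        assert loglik_stationary(std_normal_mixture, []) == 0.0

    def test_true_model_scores_higher_than_shifted(self):
        """Gibbs' inequality: draws from A score better under A than A-shifted."""
        a = MixtureParams([0.4, 0.6], [0.8, 2.0], [0.09, 0.16])
        shifted = MixtureParams([0.4, 0.6], [1.1, 2.3], [0.09, 0.16])
        draws = sample_stationary(a, 1000, seed=1)
        assert loglik_stationary(a, draws) > loglik_stationary(shifted, draws)


class TestTimecourseLoglik:
    def test_no_post_initial_days_is_empty_product(self, ou_model):
        data = TimeCourseDataset("x", (0.0,), (np.array([1.0, 1.2, 1.4]),))
        with pytest.warns(UserWarning):
            assert loglik_timecourse(ou_model, data, n_traj=10, seed=0) == 0.0

    def test_deterministic_for_fixed_seed(self, ou_model, ou_dataset):
        a = loglik_timecourse(ou_model, ou_dataset, n_traj=300, dt=0.02, seed=5)
        b = loglik_timecourse(ou_model, ou_dataset, n_traj=300, dt=0.02, seed=5)
        assert a == b

    def test_evaluator_matches_function_bitwise(self, ou_model, ou_dataset):
        ev = TimecourseLikelihood(ou_dataset, n_traj=300, dt=0.02, seed=5)
        assert ev(ou_model) == loglik_timecourse(
            ou_model, ou_dataset, n_traj=300, dt=0.02, seed=5
        )

    def test_matches_ou_transition_density(self, ou_model, ou_dataset):
        """Simulation+KDE likelihood vs the exact OU propagated-KDE density."""
        approx = loglik_timecourse(ou_model, ou_dataset, n_traj=50_000, dt=0.005, seed=6)
        kde0 = GaussianKDE1D(ou_dataset.samples[0])
        mu = ou_model.mixture.means[0]
        var = ou_model.mixture.variances[0]
        exact = sum(
            float(np.sum(ou_day_logpdf(
                ou_dataset.samples[r], kde0.data, kde0.bandwidth,
                mu, var, ou_model.noise, ou_dataset.times[r],
            )))
            for r in (1, 2)
        )
        # per-cell agreement within 1%: KDE smoothing + Euler bias + MC noise
        n_cells = sum(ou_dataset.n_per_day[1:])
        assert approx / n_cells == pytest.approx(exact / n_cells, abs=0.01 * abs(exact / n_cells) + 0.01)

    def test_stiff_parameters_hit_the_divergence_floor(self, ou_dataset):
        """B/var >> 1/dt makes Euler-Maruyama blow up; such parameter corners
        must score at the floor instead of crashing the sampler."""
        stiff = StochasticModel(
            MixtureParams([1.0], [1.5], [0.05**2]), noise=3.0
        )
        ev = TimecourseLikelihood(ou_dataset, n_traj=300, dt=0.02, seed=5)
        ll = ev(stiff)
        n_obs = sum(ou_dataset.n_per_day[1:])
        assert ll == -700.0 * n_obs
        assert loglik_timecourse(stiff, ou_dataset, n_traj=300, dt=0.02, seed=5) == ll

    def test_monte_carlo_variance_shrinks_with_ensemble_size(self, ou_model, ou_dataset):
        small = [loglik_timecourse(ou_model, ou_dataset, n_traj=1000, dt=0.02, seed=s)
                 for s in range(10)]
        large = [loglik_timecourse(ou_model, ou_dataset, n_traj=8000, dt=0.02, seed=s)
                 for s in range(10)]
        assert np.var(large) < np.var(small)

    def test_agrees_with_grid_solver_of_evolution_equation(self, ou_model):
        """Per-day mean log density vs a Crank-Nicolson forward solution."""
        mix = MixtureParams([0.5, 0.5], [1.0, 2.0], [0.04, 0.04])
        model = StochasticModel(mix, noise=0.25)
        init = InitialSpec("sorted_fraction", center=1.4, width=0.1)
        data = generate_timecourse(model, init, [0, 1, 2], 800, dt=0.005, seed=22)
        kde0 = GaussianKDE1D(data.samples[0])

        from nanoscape._kernels import em_segment

        x_grid = np.linspace(-1.0, 4.0, 2001)
        ens = TimecourseLikelihood(data, n_traj=40_000, dt=0.005, seed=23)
        x = ens.x0.copy()
        logw = np.log(np.asarray(mix.weights))
        for r in (1, 2):
            em_segment(x, ens.normals[r - 1], ens.dt,
                       np.sqrt(2 * model.noise * ens.dt), logw,
                       np.asarray(mix.means), np.asarray(mix.variances),
                       model.noise)
            sim_mean = float(np.mean(GaussianKDE1D(x).logpdf(data.samples[r])))
            p = evolve_density_cn(
                lambda z: np.asarray(model.drift(z)), model.noise, kde0.pdf,
                x_grid, data.times[r], dt=0.002,
            )
            pde_mean = float(np.mean(np.log(np.interp(data.samples[r], x_grid, p))))
            assert sim_mean == pytest.approx(pde_mean, rel=0.02)


class TestDatasetContainer:
    def test_requires_day_zero(self):
        with pytest.raises(ValueError):
            TimeCourseDataset("x", (1.0, 2.0), (np.ones(3), np.ones(3)))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            TimeCourseDataset("x", (0.0, 1.0), (np.ones(3), np.array([1.0, np.nan])))

    def test_tidy_csv_roundtrip(self, tmp_path, ou_dataset):
        path = tmp_path / "tc.csv"
        ou_dataset.to_csv(path)
        again = TimeCourseDataset.from_csv(path)
        assert again.condition == ou_dataset.condition
        assert again.times == ou_dataset.times
        for a, b in zip(again.samples, ou_dataset.samples):
            np.testing.assert_allclose(a, b, rtol=1e-12)
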