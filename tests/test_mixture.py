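"""Stationary mixture density, potential, drift and sampling."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanoscape import (
    MixtureParams,
    StochasticModel,
    drift,
    log_mixture_density,
    mixture_density,
    potential,
    reference_model,
    sample_stationary,
)

from oracles import finite_difference_drift, mixture_pdf_termwise, mixture_tail_mass


@st.composite
def mixture_params(draw):
    k = draw(st.integers(1, 4))
    raw_w = draw(st.lists(st.floats(0.05, 1.0), min_size=k, max_size=k))
    w = np.asarray(raw_w) / np.sum(raw_w)
    means = np.cumsum(draw(st.lists(st.floats(0.2, 1.5), min_size=k, max_size=k)))
    variances = draw(st.lists(st.floats(0.01, 2.0), min_size=k, max_size=k))
    return MixtureParams(w, means, variances)


class TestMixtureDensity:
    def test_standard_normal_mode(self, std_normal_mixture):
        assert mixture_density(std_normal_mixture, 0.0) == pytest.approx(0.398942, abs=1e-6)

    def test_symmetric_bimodal_midpoint(self, symmetric_bimodal):
        # at the symmetry point both components contribute the normal density at 1
        assert mixture_density(symmetric_bimodal, 0.0) == pytest.approx(0.241971, abs=1e-6)

    def test_published_self_renewal_row_termwise(self):
        """Three-component density matches an independent term-by-term sum."""
        m = reference_model("LIF+BMP4").mixture
        expected = 0.4404876075020006  # frozen from the termwise oracle
        assert mixture_density(m, 1.80) == pytest.approx(expected, rel=1e-12)
        grid = np.linspace(-0.5, 3.5, 101)
        np.testing.assert_allclose(
            mixture_density(m, grid),
            mixture_pdf_termwise(m.weights, m.means, m.variances, grid),
            rtol=1e-12,
        )

    def test_rejects_non_finite_x(self, std_normal_mixture):
        with pytest.raises(ValueError):
            mixture_density(std_normal_mixture, np.nan)
        with pytest.raises(ValueError):
            log_mixture_density(std_normal_mixture, np.inf)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(params=mixture_params())
    def test_normalizes_to_one(self, params):
        sd_max = np.sqrt(max(params.variances))
        lo = min(params.means) - 10 * sd_max
        hi = max(params.means) + 10 * sd_max
        x = np.linspace(lo, hi, 4001)
        integral = np.trapezoid(mixture_density(params, x), x)
        assert integral == pytest.approx(1.0, abs=1e-6)


class TestLogDensity:
    def test_standard_normal_at_zero(self, std_normal_mixture):
        assert log_mixture_density(std_normal_mixture, 0.0) == pytest.approx(-0.918939, abs=1e-6)

    def test_far_tail_does_not_underflow(self, std_normal_mixture):
        # closed form -x^2/2 - log(sqrt(2 pi)); the direct density is 0 here
        assert log_mixture_density(std_normal_mixture, 40.0) == pytest.approx(
            -800.918939, abs=1e-5
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(params=mixture_params())
    def test_exp_log_consistency(self, params):
        x = np.linspace(min(params.means) - 3, max(params.means) + 3, 41)
        np.testing.assert_allclose(
            np.exp(log_mixture_density(params, x)), mixture_density(params, x), rtol=1e-12
        )


class TestPotentialAndDrift:
    def test_potential_of_standard_normal(self, std_normal_mixture):
        model = StochasticModel(std_normal_mixture, noise=1.0)
        assert potential(model, 0.0) == pytest.approx(0.918939, abs=1e-6)

    def test_potential_linear_in_noise(self, symmetric_bimodal):
        x = np.linspace(-4, 4, 101)
        m1 = StochasticModel(symmetric_bimodal, noise=0.25)
        m2 = StochasticModel(symmetric_bimodal, noise=0.5)
        np.testing.assert_array_equal(2.0 * potential(m1, x), potential(m2, x))

    def test_noise_scaling_preserves_stationary_density(self, symmetric_bimodal):
        """Same mixture with 4B: identical p_s, potential scaled exactly by 4."""
        x = np.linspace(-4, 4, 201)
        m = StochasticModel(symmetric_bimodal, noise=0.3)
        m4 = StochasticModel(symmetric_bimodal, noise=4 * 0.3)
        np.testing.assert_array_equal(
            mixture_density(m.mixture, x), mixture_density(m4.mixture, x)
        )
        np.testing.assert_array_equal(4.0 * potential(m, x), potential(m4, x))

    def test_dominant_state_is_global_minimum(self):
        """With 91.6% occupancy at the high state, U is lowest at its mean."""
        model = reference_model("2i")
        grid = np.linspace(0.0, 3.0, 3001)
        u = potential(model, grid)
        mu_hn = model.mixture.means[-1]
        # the minimum sits at the dominant mean up to the tilt of the
        # neighbouring components
        assert abs(grid[np.argmin(u)] - mu_hn) < 0.02
        assert potential(model, mu_hn) <= u.min() + 1e-3

    def test_ou_drift_closed_form(self):
        mu, var, B = 1.5, 0.16, 0.4
        model = StochasticModel(MixtureParams([1.0], [mu], [var]), noise=B)
        x = np.linspace(-1, 4, 41)
        np.testing.assert_allclose(drift(model, x), -B * (x - mu) / var, rtol=1e-12)
        assert drift(model, mu) == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_mixture_zero_drift_at_midpoint(self, symmetric_bimodal):
        model = StochasticModel(symmetric_bimodal, noise=0.7)
        assert drift(model, 0.0) == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("condition", ["LIF+BMP4", "PD03", "Chiron", "2i"])
    def test_drift_matches_finite_difference_of_potential(self, condition):
        model = reference_model(condition)
        x = np.linspace(-0.5, 3.5, 201)
        fd = finite_difference_drift(lambda z: potential(model, z), x)
        np.testing.assert_allclose(drift(model, x), fd, atol=1e-6)


class TestSampling:
    def test_deterministic_under_fixed_seed(self, symmetric_bimodal):
        a = sample_stationary(symmetric_bimodal, 5, seed=123)
        b = sample_stationary(symmetric_bimodal, 5, seed=123)
        np.testing.assert_array_equal(a, b)

    def test_degenerate_variance_concentrates(self):
        params = MixtureParams([1.0], [2.0], [1e-12])
        draws = sample_stationary(params, 100, seed=0)
        np.testing.assert_allclose(draws, 2.0, atol=1e-4)

    def test_rejects_nonpositive_n(self, std_normal_mixture):
        with pytest.raises(ValueError):
            sample_stationary(std_normal_mixture, 0, seed=0)

    def test_tail_mass_matches_analytic_cdf(self):
        """200k draws from the Chiron landscape vs the analytic tail mass."""
        m = reference_model("Chiron").mixture
        draws = sample_stationary(m, 200_000, seed=42)
        expected = mixture_tail_mass(m.weights, m.means, m.variances, 2.0)
        assert expected == pytest.approx(0.5201808303102033, abs=1e-12)
        assert np.mean(draws > 2.0) == pytest.approx(expected, abs=0.005)


class TestConstructionAndSerialization:
    def test_means_canonicalized_ascending(self):
        p = MixtureParams([0.2, 0.8], [2.0, 1.0], [0.3, 0.1])
        assert p.means == (1.0, 2.0)
        assert p.weights == (0.8, 0.2)
        assert p.variances == (0.1, 0.3)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureParams([0.5, 0.4], [0.0, 1.0], [1.0, 1.0])

    def test_variances_must_be_positive(self):
        with pytest.raises(ValueError):
            MixtureParams([1.0], [0.0], [-1.0])

    def test_duplicate_means_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams([0.5, 0.5], [1.0, 1.0], [0.1, 0.2])

    def test_json_roundtrip_bit_exact(self):
        model = StochasticModel(
            MixtureParams([0.25, 0.75], [0.123456789012345, 2.5], [0.111, 0.222]),
            noise=0.86,
        )
        again = StochasticModel.from_json(model.to_json())
        assert again.mixture.weights == model.mixture.weights
        assert again.mixture.means == model.mixture.means
        assert again.mixture.variances == model.mixture.variances
        assert again.noise == model.noise
        d = json.loads(model.to_json())
        assert set(d) == {"k", "weights", "means", "variances", "noise"}
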