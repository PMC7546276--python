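"""Transforms, covariate model, residual error and the M3 likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from vitapk import (
    IndividualRealization,
    Observation,
    apply_covariate_V1,
    compile_dataset,
    dataset_loglik,
    default_feline_model,
    observation_loglik,
    residual_sd,
    transform_parameter,
)
from vitapk.population import (
    RESIDUAL_FLOOR,
    inv_logit,
    logit,
    loglik_terms,
)
from vitapk.structural import InvalidParameterError


class TestTransforms:
    def test_log_identity_at_zero_deviation(self):
        assert transform_parameter(2.88, 0.0, "log") == pytest.approx(2.88)

    def test_logit_identity_at_half(self):
        assert transform_parameter(0.5, 0.0, "logit") == pytest.approx(0.5)
        assert logit(0.5) == 0.0

    @pytest.mark.parametrize("x", [0.01, 0.20, 0.578, 0.99])
    def test_logit_round_trip(self, x):
        assert float(inv_logit(logit(x))) == pytest.approx(x, abs=1e-12)

    def test_logit_requires_open_unit_interval(self):
        with pytest.raises(InvalidParameterError):
            transform_parameter(1.2, 0.0, "logit")

    @given(st.floats(-10, 10), st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_logit_transformed_values_stay_bounded(self, dev, mu):
        phi = transform_parameter(mu, dev, "logit")
        assert 0.0 < phi < 1.0

    def test_log_normal_draws_have_symmetric_logs(self, rng):
        model = default_feline_model()
        draws = model.mu["V1"] * np.exp(rng.normal(0, 0.3, 100_000))
        assert abs(stats.skew(np.log(draws))) < 0.05


class TestCovariateModel:
    def test_centered_bodyweight_returns_population_value(self):
        assert apply_covariate_V1(2.88, 0.41, 2.9, 2.9, 0.0) == pytest.approx(2.88)

    def test_unit_coded_covariate_scales_exponentially(self):
        # c(WT0) = 1 when WT0 = e * reference under the log-ratio coding
        v = apply_covariate_V1(2.88, 0.41, 2.9 * math.e, 2.9, 0.0)
        assert v == pytest.approx(2.88 * math.exp(0.41), rel=1e-12)
        assert v == pytest.approx(4.34, abs=5e-3)

    def test_monotone_increasing_in_bodyweight(self):
        weights = [1.5, 2.0, 2.9, 4.0, 6.0]
        vals = [apply_covariate_V1(2.88, 0.41, w, 2.9) for w in weights]
        assert np.all(np.diff(vals) > 0)

    def test_raw_coding_available(self):
        v = apply_covariate_V1(2.88, 0.1, 3.0, 2.9, coding="raw")
        assert v == pytest.approx(2.88 * math.exp(0.1 * 3.0))

    def test_nonpositive_bodyweight_rejected(self):
        with pytest.raises(ValueError):
            apply_covariate_V1(2.88, 0.41, -1.0, 2.9)


class TestResidualError:
    def test_proportional_scale(self):
        assert float(residual_sd(100.0, 0.30)) == pytest.approx(30.0)

    def test_floor_at_zero_prediction(self):
        assert float(residual_sd(0.0, 0.30)) == RESIDUAL_FLOOR

    def test_linearity_above_floor(self):
        assert float(residual_sd(80.0, 0.30)) == pytest.approx(
            2 * float(residual_sd(40.0, 0.30))
        )


class TestM3Likelihood:
    def test_density_at_the_mean(self):
        g = 0.3 * 100.0
        ll = observation_loglik(Observation(1.0, 100.0), 100.0, 0.3)
        assert ll == pytest.approx(-math.log(g * math.sqrt(2 * math.pi)))

    def test_censored_term_far_above_lloq_is_clamped(self):
        ll = observation_loglik(
            Observation(1.0, 0.5, blq=True, lloq=0.5), 1e4, 0.01
        )
        assert ll == pytest.approx(math.log(1e-300))

    def test_censored_probability_is_valid(self, rng):
        for _ in range(100):
            pred = float(np.exp(rng.uniform(-3, 3)))
            b = float(rng.uniform(0.05, 1.0))
            ll = observation_loglik(
                Observation(1.0, 0.5, blq=True, lloq=0.5), pred, b
            )
            assert ll <= 0.0  # a probability, at most 1

    def test_censored_term_matches_quadrature(self, rng):
        for _ in range(50):
            pred = float(np.exp(rng.uniform(math.log(0.01), math.log(5.0))))
            b = float(rng.uniform(0.05, 0.8))
            g = float(residual_sd(pred, b))
            ll = observation_loglik(
                Observation(1.0, 0.5, blq=True, lloq=0.5), pred, b
            )
            prob, _ = integrate.quad(
                lambda x: stats.norm.pdf(x, loc=pred, scale=g), 0.0, 0.5,
                epsabs=1e-14, epsrel=1e-12,
            )
            assert ll == pytest.approx(math.log(prob), abs=1e-8)

    def test_uncensored_terms_equal_gaussian_closed_form(self, rng):
        dv = rng.uniform(1, 100, 20)
        pred = rng.uniform(1, 100, 20)
        ll = loglik_terms(dv, pred, np.zeros(20, bool), np.full(20, 0.5), 0.3)
        ref = stats.norm.logpdf(dv, loc=pred, scale=0.3 * pred)
        np.testing.assert_allclose(ll, ref, rtol=1e-12)


class TestDatasetLoglik:
    def test_empty_dataset_gives_zero(self, generating_model):
        assert dataset_loglik([], generating_model, {}) == 0.0

    def test_missing_realization_raises(self, small_subjects, generating_model):
        with pytest.raises(KeyError):
            dataset_loglik(small_subjects, generating_model, {})

    def test_matches_brute_force_summation(self, small_subjects, generating_model):
        rng = np.random.default_rng(0)
        model = generating_model
        reals = {}
        for sub in small_subjects:
            eta = {p: rng.normal(0, 0.1) for p in model.parameters}
            kappa = {
                occ.label: {p: rng.normal(0, 0.1) for p in model.parameters}
                for occ in sub.occasions
            }
            reals[sub.sid] = IndividualRealization(eta=eta, kappa=kappa)
        total = dataset_loglik(small_subjects, model, reals)

        # independent per-observation summation through the scalar API
        from vitapk.population import occasion_predictions

        brute = 0.0
        for sub in small_subjects:
            real = reals[sub.sid]
            for occ in sub.occasions:
                phi = model.individual_params(
                    sub.covs, real.eta, real.kappa[occ.label]
                )
                pred = occasion_predictions(
                    model, occ, np.array([phi[p] for p in model.parameters])
                )
                for j in range(occ.n_obs):
                    brute += observation_loglik(
                        Observation(
                            occ.times[j], occ.dv[j],
                            blq=bool(occ.blq[j]), lloq=occ.lloq[j],
                        ),
                        float(pred[j]), model.b,
                    )
        assert total == pytest.approx(brute, rel=1e-12)
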