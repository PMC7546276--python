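"""SAEM engine: kernels, importance sampling, BIC, recovery contracts."""

import math

import numpy as np
import pytest

from vitapk import (
    build_designs,
    compile_dataset,
    compute_bic,
    compute_rse,
    default_feline_model,
    initial_estimates,
    loglik_importance_sampling,
    mcmc_individual_step,
    saem_fit,
    simulate_dataset,
    stabilize_random_effects,
)
from vitapk.population import PARAM_ORDER, PARAM_ORDER_1CPT
from vitapk.saem import (
    SAEMConfig,
    fd_hessian,
    importance_sampling_loglik,
    mh_update,
)


class TestMHKernel:
    def test_identity_proposal_always_accepted(self, rng):
        x, lp, accepted = mh_update(1.5, lambda v: -0.5 * v * v, 0.0, rng)
        assert accepted and x == 1.5

    def test_nonfinite_proposal_rejected(self, rng):
        def logpost(v):
            return -math.inf if v != 0.0 else 0.0

        x, lp, accepted = mh_update(0.0, logpost, 1.0, rng)
        assert x == 0.0 and not accepted

    def test_chain_matches_conjugate_normal_posterior(self, rng):
        # y_j ~ N(theta, s2), theta ~ N(0, w2): posterior is closed form
        y = rng.normal(1.0, 0.5, 20)
        s2, w2 = 0.25, 1.0
        post_var = 1.0 / (len(y) / s2 + 1.0 / w2)
        post_mean = post_var * y.sum() / s2

        def logpost(th):
            return -0.5 * np.sum((y - th) ** 2) / s2 - 0.5 * th * th / w2

        chain = []
        x, lp = 0.0, logpost(0.0)
        for _ in range(20000):
            x, lp, _ = mh_update(x, logpost, 0.3, rng, current_logpost=lp)
            chain.append(x)
        chain = np.asarray(chain[2000:])
        assert chain.mean() == pytest.approx(post_mean, abs=4 * math.sqrt(post_var / 200))
        assert chain.var() == pytest.approx(post_var, rel=0.15)

    def test_single_subject_sweep_runs(self, small_subjects, generating_model, rng):
        sub = small_subjects[0]
        P = len(generating_model.parameters)
        eta = np.zeros(P)
        kappa = np.zeros((P, len(sub.occasions)))
        eta2, kappa2, ll = mcmc_individual_step(
            sub, (eta, kappa), generating_model, rng, reps=2
        )
        assert eta2.shape == (P,) and np.all(np.isfinite(ll))
        assert not np.allclose(eta2, 0.0)  # something moved


class TestImportanceSampling:
    def _toy(self, rng, n_obs=10, omega2=1.0, s2=0.25):
        y = rng.normal(0.5, math.sqrt(s2 + omega2), n_obs)

        def loglik_fn(draws):
            z = draws[:, 0][:, None]
            return -0.5 * np.sum(
                (y - 1.0 - z) ** 2 / s2 + math.log(2 * math.pi * s2), axis=1
            )

        # closed-form marginal: y ~ N(1, s2 I + omega2 J)
        cov = s2 * np.eye(n_obs) + omega2
        resid = y - 1.0
        _, logdet = np.linalg.slogdet(cov)
        exact = -0.5 * (
            resid @ np.linalg.solve(cov, resid) + logdet + n_obs * math.log(2 * math.pi)
        )
        return loglik_fn, exact

    def test_linear_gaussian_closed_form(self, rng):
        loglik_fn, exact = self._toy(rng)
        ll, se, ess = importance_sampling_loglik(
            loglik_fn, np.array([1.0]), np.array([0.0]), np.array([2.0]),
            4000, rng,
        )
        assert ll == pytest.approx(exact, abs=max(3 * se, 0.05))
        assert ess > 100

    def test_monte_carlo_error_shrinks_with_samples(self, rng):
        loglik_fn, _ = self._toy(rng)
        _, se_small, _ = importance_sampling_loglik(
            loglik_fn, np.array([1.0]), np.array([0.0]), np.array([2.0]), 500, rng
        )
        _, se_big, _ = importance_sampling_loglik(
            loglik_fn, np.array([1.0]), np.array([0.0]), np.array([2.0]), 8000, rng
        )
        assert se_big < se_small

    def test_no_random_effects_reduces_to_exact_loglik(self, small_subjects):
        from vitapk import IndividualRealization, dataset_loglik
        from vitapk.saem import FitResult
        import pandas as pd

        model = default_feline_model().with_updates(
            omega2={p: 0.0 for p in PARAM_ORDER},
            gamma2={p: 0.0 for p in PARAM_ORDER},
        )
        fit = FitResult(
            model=model, loglik=np.nan, loglik_se=np.nan, bic=np.nan,
            n_params=0, n_subjects=len(small_subjects),
            ebes=pd.DataFrame(), etas=pd.DataFrame(),
            trajectories=pd.DataFrame(), converged=True,
        )
        ll, se, _ = loglik_importance_sampling(small_subjects, fit, 10)
        reals = {
            sub.sid: IndividualRealization(
                eta={}, kappa={occ.label: {} for occ in sub.occasions}
            )
            for sub in small_subjects
        }
        assert ll == pytest.approx(dataset_loglik(small_subjects, model, reals))
        assert se == 0.0


class TestModelMetrics:
    def test_bic_arithmetic(self):
        assert compute_bic(-100.0, 10, 16) == pytest.approx(227.726, abs=1e-3)

    def test_bic_monotone_in_parameters(self):
        assert compute_bic(-100.0, 12, 16) > compute_bic(-100.0, 10, 16)

    def test_bic_with_no_parameters(self):
        assert compute_bic(-100.0, 0, 16) == 200.0

    def test_stabilization_rule(self):
        adjusted, fixed = stabilize_random_effects(
            {"CL": (5e-5) ** 2, "V1": 0.09}, threshold=1e-4, fix_sd=0.1
        )
        assert adjusted["CL"] == pytest.approx(0.01)
        assert adjusted["V1"] == 0.09
        assert fixed == {"CL"}

    def test_all_degenerate_random_effects_are_fixed(self):
        adjusted, fixed = stabilize_random_effects({"a": 0.0, "b": 1e-12})
        assert fixed == {"a", "b"}
        assert all(v == pytest.approx(0.01) for v in adjusted.values())

    def test_fd_hessian_on_quadratic(self):
        A = np.array([[2.0, 0.3], [0.3, 1.0]])

        def f(x):
            return -0.5 * x @ A @ x

        H = fd_hessian(f, np.zeros(2), h=0.05)
        np.testing.assert_allclose(H, -A, atol=1e-8)


@pytest.fixture(scope="module")
def tiny_fit_inputs():
    designs = build_designs({"studies": ["S1", "S2"], "n_subjects": 3})
    data = simulate_dataset(designs, model=default_feline_model(), seed=11)
    subs = compile_dataset(data.dataset)
    cfg = SAEMConfig(
        n_exploratory=30, n_smoothing=20, n_chains=2, seed=9,
        loglik_is_samples=50,
    )
    return subs, cfg


class TestSAEMFit:
    def test_same_seed_gives_identical_fit(self, tiny_fit_inputs):
        subs, cfg = tiny_fit_inputs
        f1 = saem_fit(subs, cfg)
        f2 = saem_fit(subs, cfg)
        assert f1.model.mu == f2.model.mu
        assert f1.model.b == f2.model.b
        assert f1.loglik == f2.loglik
        assert f1.ebes.equals(f2.ebes)

    def test_different_seed_gives_different_fit(self, tiny_fit_inputs):
        subs, cfg = tiny_fit_inputs
        f1 = saem_fit(subs, cfg)
        f3 = saem_fit(subs, SAEMConfig(**{**cfg.__dict__, "seed": 10}))
        assert f1.model.mu != f3.model.mu

    def test_exploratory_moves_and_smoothing_settles(self, tiny_fit_inputs):
        subs, _ = tiny_fit_inputs
        cfg = SAEMConfig(
            n_exploratory=150, n_smoothing=120, n_chains=2, seed=4,
            loglik_is_samples=50,
        )
        fit = saem_fit(subs, cfg, compute_loglik=False)
        tr = fit.trajectories
        expl = tr[tr.phase == "exploratory"]["CL"].to_numpy()
        smoo = tr[tr.phase == "smoothing"]["CL"].to_numpy()[-50:]
        assert expl.std() > 0
        drift = np.max(np.abs(smoo - smoo[-1])) / abs(smoo[-1])
        assert drift < 0.3
        assert smoo.std() < expl.std()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            saem_fit([], SAEMConfig(n_exploratory=1, n_smoothing=1))

    def test_noise_free_recovery(self):
        """With variability off and tiny error, the fixed effects come back."""
        truth = default_feline_model().with_updates(
            b=0.002, beta_V1_WT0=0.0,
            omega2={p: 0.0 for p in PARAM_ORDER},
            gamma2={p: 0.0 for p in PARAM_ORDER},
        )
        designs = build_designs({"studies": ["S1", "S2"]})
        data = simulate_dataset(designs, model=truth, seed=7)
        subs = compile_dataset(data.dataset)
        init = initial_estimates(subs).with_updates(
            omega2={p: 1e-4 for p in PARAM_ORDER},
            gamma2={p: 1e-4 for p in PARAM_ORDER},
        )
        cfg = SAEMConfig(
            n_exploratory=200, n_smoothing=300, seed=2,
            loglik_is_samples=100, fixed_inflation=0.0,
        )
        fit = saem_fit(subs, cfg, init=init, estimate_covariate=False,
                       compute_loglik=False, fix_variances=True)
        for p in PARAM_ORDER:
            assert fit.model.mu[p] == pytest.approx(truth.mu[p], rel=0.02), p

    def test_one_compartment_variant_fits(self, tiny_fit_inputs):
        subs, _ = tiny_fit_inputs
        init = initial_estimates(subs, parameters=PARAM_ORDER_1CPT)
        cfg = SAEMConfig(
            n_exploratory=30, n_smoothing=20, n_chains=2, seed=3,
            loglik_is_samples=100,
        )
        fit = saem_fit(subs, cfg, init=init, estimate_covariate=False)
        assert set(fit.model.mu) == set(PARAM_ORDER_1CPT)
        assert np.isfinite(fit.bic)


def test_bic_prefers_generating_structure_over_one_compartment():
    """Model comparison: BIC picks the two-compartment truth (majority rule)."""
    from vitapk.experiments import bic_model_comparison

    assert bic_model_comparison(n_seeds=3, seed=0) >= 2 / 3


class TestRSE:
    def test_rich_data_gives_small_rse(self):
        """Many low-noise curves drive the standard errors toward zero."""
        truth = default_feline_model().with_updates(
            b=0.01, beta_V1_WT0=0.0,
            omega2={p: 0.0 for p in PARAM_ORDER},
            gamma2={p: 0.0 for p in PARAM_ORDER},
        )
        designs = build_designs({"studies": ["S1", "S2"]})
        data = simulate_dataset(designs, model=truth, seed=5)
        subs = compile_dataset(data.dataset)
        from vitapk.saem import FitResult
        import pandas as pd

        fit = FitResult(
            model=truth, loglik=np.nan, loglik_se=np.nan, bic=np.nan,
            n_params=0, n_subjects=len(subs), ebes=pd.DataFrame(),
            etas=pd.DataFrame(), trajectories=pd.DataFrame(), converged=True,
        )
        rse = compute_rse(fit, subs, n_samples=1, step=0.02, seed=0)
        finite = {k: v for k, v in rse.items() if np.isfinite(v)}
        assert len(finite) >= 8
        assert all(v < 10.0 for v in finite.values())  # percent

    def test_toy_information_matches_analytic(self, rng):
        """FD curvature of an exact Gaussian log-likelihood gives the
        textbook standard error of a mean."""
        n, sigma = 50, 0.4
        y = rng.normal(2.0, sigma, n)

        def loglik(theta):
            return float(
                -0.5 * np.sum((y - theta[0]) ** 2) / sigma ** 2
                - n * math.log(sigma * math.sqrt(2 * math.pi))
            )

        H = fd_hessian(loglik, np.array([y.mean()]), h=0.01)
        se = math.sqrt(-1.0 / H[0, 0])
        assert se == pytest.approx(sigma / math.sqrt(n), rel=0.1)
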