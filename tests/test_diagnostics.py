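"""Residual diagnostics, prediction bands and the covariate screen."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitapk import (
    build_designs,
    compile_dataset,
    compute_iwres,
    compute_npde,
    covariate_screen,
    default_feline_model,
    eta_correlation_screen,
    estimate_etas_map,
    prediction_distribution,
    simulate_dataset,
)
from vitapk.saem import posterior_mean_etas
from vitapk.synth import batch_simulate_subject


class TestIWRES:
    def test_zero_residual(self):
        assert compute_iwres(np.array([100.0]), np.array([100.0]), 0.3)[0] == 0.0

    def test_unit_residual(self):
        iw = compute_iwres(np.array([130.0]), np.array([100.0]), 0.30)
        assert iw[0] == pytest.approx(1.0)

    def test_calibration_under_true_model(self, rng):
        from vitapk.population import residual_sd

        pred = np.exp(rng.uniform(0, 6, 10_000))
        y = pred + residual_sd(pred, 0.3) * rng.standard_normal(10_000)
        iw = compute_iwres(y, pred, 0.3)
        assert abs(iw.mean()) < 0.05
        assert abs(iw.var() - 1.0) < 0.1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_iwres(np.zeros(3), np.zeros(2), 0.3)


class TestNPDE:
    def test_boundary_rank_value(self, generating_model):
        # craft a dataset whose only observation sits far below every
        # simulation: the NPDE must be the clipped lower-boundary quantile
        designs = build_designs({"studies": ["S1"], "n_subjects": 1})
        data = simulate_dataset([designs[0]], model=generating_model, seed=0)
        df = data.dataset.df
        obs_rows = df[df.MDV == 0].index
        df.loc[obs_rows, "DV"] = 0.6  # above LLOQ but far below the model
        subs = compile_dataset(data.dataset)
        K = 100
        npde, _ = compute_npde(subs, generating_model, n_simulations=K, seed=1)
        assert npde.min() == pytest.approx(stats.norm.ppf(0.5 / K))

    def test_minimum_simulation_count_enforced(self, full_subjects, generating_model):
        with pytest.raises(ValueError):
            compute_npde(full_subjects, generating_model, n_simulations=50)

    def test_true_model_npde_close_to_standard_normal(
        self, full_subjects, generating_model
    ):
        npde, flags = compute_npde(
            full_subjects, generating_model, n_simulations=400, seed=2
        )
        assert not flags
        assert abs(npde.mean()) < 0.15
        assert abs(npde.var() - 1.0) < 0.25

    def test_deterministic_under_fixed_seed(self, full_subjects, generating_model):
        a, _ = compute_npde(full_subjects, generating_model, 150, seed=3)
        b, _ = compute_npde(full_subjects, generating_model, 150, seed=3)
        np.testing.assert_array_equal(a, b)


class TestPredictionBands:
    def test_bands_nested_and_monotone(self, full_subjects, generating_model):
        bands = prediction_distribution(
            full_subjects[:2], generating_model, n_replicates=200, seed=0
        )
        for frame in bands.values():
            qcols = sorted(c for c in frame.columns if c.startswith("q"))
            mat = frame[qcols].to_numpy()
            assert np.all(np.diff(mat, axis=1) >= 0)

    def test_zero_variability_band_collapses_to_typical_curve(self):
        model = default_feline_model(omega=0.0, gamma=0.0).with_updates(
            b=1e-9, beta_V1_WT0=0.0
        )
        designs = build_designs({"studies": ["S1"], "n_subjects": 1})
        data = simulate_dataset(designs, model=model, seed=0)
        subs = compile_dataset(data.dataset)
        bands = prediction_distribution(subs, model, n_replicates=50, seed=0)
        frame = next(iter(bands.values()))
        from vitapk.population import occasion_predictions

        occ = subs[0].occasions[0]
        phi = np.array([model.mu[p] for p in model.parameters])
        m = model.m_vector() + model.covariate_offsets(subs[0].covs.WT0)
        typical = occasion_predictions(model, occ, model.phi_from_psi(m))
        np.testing.assert_allclose(frame["q05"], typical, rtol=1e-6)
        np.testing.assert_allclose(frame["q95"], typical, rtol=1e-6)


class TestEtaCorrelationScreen:
    def test_identical_vectors_give_unit_correlation(self):
        etas = pd.DataFrame({
            "ID": range(10),
            "CL": np.arange(10.0),
            "V1": np.arange(10.0),
        })
        out = eta_correlation_screen(etas)
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_independent_normals_are_uncorrelated(self, rng):
        etas = pd.DataFrame({
            "ID": range(10_000),
            "CL": rng.standard_normal(10_000),
            "V1": rng.standard_normal(10_000),
        })
        out = eta_correlation_screen(etas)
        assert abs(out.r.iloc[0]) < 0.05

    def test_matches_textbook_formulas(self, rng):
        """r and P recomputed from first principles (t distribution)."""
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            etas = pd.DataFrame({"ID": range(n), "a": x, "b": y})
            out = eta_correlation_screen(etas).iloc[0]
            xc, yc = x - x.mean(), y - y.mean()
            r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert out.r == pytest.approx(r, abs=1e-10)
            assert out.p_value == pytest.approx(p, abs=1e-8)

    def test_zero_variance_pair_skipped(self):
        etas = pd.DataFrame({"ID": range(5), "a": np.ones(5), "b": np.arange(5.0)})
        out = eta_correlation_screen(etas)
        assert bool(out.skipped.iloc[0])

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError):
            eta_correlation_screen(pd.DataFrame({"ID": [1, 2], "a": [0.1, 0.2]}))


class TestCovariateScreen:
    @staticmethod
    def _covs(n, rng, constant_fed=False):
        return pd.DataFrame({
            "ID": range(n),
            "WT0": np.exp(rng.normal(1.0, 0.25, n)),
            "SEX": rng.choice(["m", "f"], n),
            "FED": ["fasted"] * n if constant_fed
            else rng.choice(["fasted", "fed"], n),
        })

    def test_constant_covariate_skipped(self, rng):
        covs = self._covs(16, rng, constant_fed=True)
        etas = pd.DataFrame({"ID": range(16), "CL": rng.standard_normal(16)})
        out = covariate_screen(etas, covs)
        fed = out[(out.covariate == "FED")]
        assert fed.skipped.all()

    def test_planted_bodyweight_effect_is_detected(self, rng):
        n = 60
        covs = self._covs(n, rng)
        x = np.log(covs["WT0"] / np.exp(np.mean(np.log(covs["WT0"]))))
        etas = pd.DataFrame({
            "ID": range(n),
            "V1": 0.41 * x + rng.normal(0, 0.1, n),
            "CL": rng.normal(0, 0.1, n),
        })
        out = covariate_screen(etas, covs)
        row = out[(out.parameter == "V1") & (out.covariate == "logWT0")]
        assert bool(row.flagged.iloc[0])

    def test_misaligned_covariates_rejected(self, rng):
        covs = self._covs(5, rng)
        etas = pd.DataFrame({"ID": range(8), "CL": rng.standard_normal(8)})
        with pytest.raises(ValueError):
            covariate_screen(etas, covs)


class TestEtaEstimators:
    def test_map_etas_track_true_etas(self, generating_model):
        data = simulate_dataset(
            build_designs(), model=generating_model, seed=21
        )
        subs = compile_dataset(data.dataset)
        screen_model = generating_model.with_updates(beta_V1_WT0=0.0)
        etas = estimate_etas_map(subs, screen_model)
        true_cl = np.array(
            [data.truth["eta"][sid]["CL"] for sid in etas["ID"]]
        )
        r, _ = stats.pearsonr(etas["CL"].to_numpy(), true_cl)
        assert r > 0.6

    def test_posterior_mean_etas_track_true_etas(self, generating_model):
        data = simulate_dataset(
            build_designs(), model=generating_model, seed=21
        )
        subs = compile_dataset(data.dataset)
        screen_model = generating_model.with_updates(beta_V1_WT0=0.0)
        etas = posterior_mean_etas(subs, screen_model, n_iter=150, burn=50, seed=0)
        true_cl = np.array(
            [data.truth["eta"][sid]["CL"] for sid in etas["ID"]]
        )
        r, _ = stats.pearsonr(etas["CL"].to_numpy(), true_cl)
        assert r > 0.6
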