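"""Goodness-of-fit and covariate-screening diagnostics.

Simulation-based model checks for the population PK model:

* individual weighted residuals (IWRES) under the proportional-error model,
* normalized prediction distribution errors (NPDE) with per-subject
  decorrelation against Monte Carlo replicates of the design,
* prediction-distribution quantile bands (the visual predictive check
  built from hundreds of replicated virtual studies),
* pairwise Pearson screening of the random-effect estimates (eta vs eta),
* the automated covariate screen: Pearson tests for continuous covariates
  and one-way ANOVA for categorical ones, flagged at P < 0.05 (no
  multiplicity correction, matching common automated screens).

All functions are deterministic given their seed/Generator argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .population import (
    CompiledSubject,
    PopulationModel,
    compile_dataset,
    occasion_predictions,
    residual_sd,
)
from .synth import batch_simulate_subject

__all__ = [
    "DiagnosticsReport",
    "compute_iwres",
    "compute_npde",
    "prediction_distribution",
    "eta_correlation_screen",
    "covariate_screen",
    "estimate_etas_map",
    "run_diagnostics",
]


@dataclass
class DiagnosticsReport:
    """Collected diagnostics for one fitted model on one dataset."""

    obs_vs_pred: pd.DataFrame
    iwres: np.ndarray
    npde: np.ndarray
    npde_flags: list
    eta_correlations: pd.DataFrame
    covariate_table: pd.DataFrame
    bands: dict = field(default_factory=dict)   # occasion label -> band frame


def compute_iwres(obs: np.ndarray, ipred: np.ndarray, b: float) -> np.ndarray:
    """Individual weighted residuals (y - F_ind) / G(F_ind).

    Expects non-BLQ observations only; under the true model these are
    standard normal.
    """
    obs = np.asarray(obs, dtype=float)
    ipred = np.asarray(ipred, dtype=float)
    if obs.shape != ipred.shape:
        raise ValueError("observations and predictions must align")
    return (obs - ipred) / residual_sd(ipred, b)


def compute_npde(
    dataset,
    model: PopulationModel,
    n_simulations: int = 500,
    seed: int | np.random.Generator = 0,
):
    """Normalized prediction distribution errors.

    Each subject's non-BLQ observation vector is compared with
    ``n_simulations`` Monte Carlo replicates of that subject under the
    model: observations and replicates are decorrelated with the empirical
    mean and Cholesky factor of the simulated covariance, each observation
    is ranked among its decorrelated replicates, and the rank is mapped
    through the standard-normal quantile function with the half-rank
    convention (rank + 0.5)/K, which keeps the extremes finite.  Subjects
    whose simulated covariance is singular fall back to uncorrelated PDEs
    and are flagged.  Returns ``(npde, flags)``.
    """
    if n_simulations < 100:
        raise ValueError("n_simulations must be at least 100")
    subjects = (
        compile_dataset(dataset) if not isinstance(dataset, list) else dataset
    )
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    out, flags = [], []
    for sub in subjects:
        sims = batch_simulate_subject(model, sub, n_simulations, rng)
        # decorrelation blocks are subject-occasions: keeps the matrix
        # dimension small relative to K so the empirical covariance does not
        # inflate the decorrelated variance
        for occ, sim_full in zip(sub.occasions, sims):
            k = ~occ.blq
            y = occ.dv[k]
            if y.size == 0:
                continue
            sim = sim_full[:, k]  # (K, n_obs)
            mu = sim.mean(axis=0)
            cov = np.atleast_2d(np.cov(sim, rowvar=False))
            try:
                L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
                y_dec = np.linalg.solve(L, y - mu)
                sim_dec = np.linalg.solve(L, (sim - mu).T).T
            except np.linalg.LinAlgError:
                flags.append(
                    f"subject {sub.sid} occasion {occ.label}: "
                    "singular simulation covariance"
                )
                sd = np.maximum(sim.std(axis=0), 1e-12)
                y_dec = (y - mu) / sd
                sim_dec = (sim - mu) / sd
            rank = (sim_dec < y_dec).sum(axis=0)
            # half-rank convention, clipped so both extremes stay finite
            rank = np.clip(rank, 0, n_simulations - 1)
            out.append(stats.norm.ppf((rank + 0.5) / n_simulations))
    return np.concatenate(out), flags


def prediction_distribution(
    subjects: Sequence[CompiledSubject],
    model: PopulationModel,
    n_replicates: int = 500,
    quantile_step: int = 5,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Prediction-distribution bands: the design replicated virtually.

    Every subject's design is simulated ``n_replicates`` times and the
    empirical quantiles (5% to 95% in steps of ``quantile_step``) of the
    simulated concentrations are computed per subject, occasion and
    timepoint.  Returns ``{(subject, occasion): DataFrame}`` with one column
    per quantile plus the median.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    qs = np.arange(quantile_step, 100, quantile_step)
    bands = {}
    for sub in subjects:
        sims = batch_simulate_subject(model, sub, n_replicates, rng)
        for occ, sim in zip(sub.occasions, sims):
            frame = pd.DataFrame({"TIME": occ.times})
            quants = np.percentile(sim, qs, axis=0)
            for q, row in zip(qs, quants):
                frame[f"q{q:02d}"] = row
            frame["median"] = np.percentile(sim, 50, axis=0)
            bands[(sub.sid, occ.label)] = frame
    return bands


def eta_correlation_screen(etas: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson correlation tests between random-effect estimates.

    ``etas`` holds one row per subject and one column per parameter.
    Zero-variance columns are skipped (flagged).  A pair is recommended for
    a covariance term when P < alpha.
    """
    cols = [c for c in etas.columns if c not in ("ID", "WT0")]
    if len(etas) < 3:
        raise ValueError("at least 3 subjects are required")
    rows = []
    for i, a in enumerate(cols):
        for b_col in cols[i + 1:]:
            x = etas[a].to_numpy(dtype=float)
            y = etas[b_col].to_numpy(dtype=float)
            if np.std(x) < 1e-12 or np.std(y) < 1e-12:
                rows.append(
                    dict(eta_1=a, eta_2=b_col, r=np.nan, p_value=np.nan,
                         flagged=False, skipped=True)
                )
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(
                dict(eta_1=a, eta_2=b_col, r=float(r), p_value=float(p),
                     flagged=bool(p < alpha), skipped=False)
            )
    return pd.DataFrame(rows)


def covariate_screen(
    etas: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    reference_bodyweight: float | None = None,
) -> pd.DataFrame:
    """Automated covariate screen on the random-effect estimates.

    Continuous covariates (bodyweight and its log-normalized form) are
    tested with Pearson's correlation; categorical covariates (sex, feeding
    status) with one-way ANOVA.  Candidates are flagged at P < alpha; no
    multiple-testing correction is applied.  Single-level categorical
    covariates and constant continuous covariates are skipped and flagged
    as such.
    """
    merged = etas.merge(covariates, on="ID", how="inner", suffixes=("", "_cov"))
    if len(merged) != len(etas):
        raise ValueError("covariates do not align with the subjects in etas")
    params = [c for c in etas.columns if c not in ("ID", "WT0")]
    wt = merged["WT0_cov"] if "WT0_cov" in merged else merged["WT0"]
    wt = wt.to_numpy(dtype=float)
    ref = reference_bodyweight or float(np.exp(np.mean(np.log(wt))))
    cont = {
        "WT0": wt,
        "logWT0": np.log(wt / ref),
    }
    cat = {k: merged[k].astype(str).to_numpy() for k in ("SEX", "FED") if k in merged}

    rows = []
    for p in params:
        e = merged[p].to_numpy(dtype=float)
        for name, x in cont.items():
            if np.std(x) < 1e-12 or np.std(e) < 1e-12:
                rows.append(dict(parameter=p, covariate=name, test="pearson",
                                 statistic=np.nan, p_value=np.nan,
                                 flagged=False, skipped=True))
                continue
            r, pv = stats.pearsonr(e, x)
            rows.append(dict(parameter=p, covariate=name, test="pearson",
                             statistic=float(r), p_value=float(pv),
                             flagged=bool(pv < alpha), skipped=False))
        for name, levels in cat.items():
            uniq = np.unique(levels)
            if uniq.size < 2:
                rows.append(dict(parameter=p, covariate=name, test="anova",
                                 statistic=np.nan, p_value=np.nan,
                                 flagged=False, skipped=True))
                continue
            groups = [e[levels == u] for u in uniq]
            f, pv = stats.f_oneway(*groups)
            rows.append(dict(parameter=p, covariate=name, test="anova",
                             statistic=float(f), p_value=float(pv),
                             flagged=bool(pv < alpha), skipped=False))
    return pd.DataFrame(rows)


def estimate_etas_map(
    dataset,
    model: PopulationModel,
    n_sweeps: int = 30,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Fast subject-level eta estimates by posterior-mode search.

    Maximizes log p(y_i | eta) + log p(eta) per subject with occasion-level
    deviations collapsed (kappa = 0), by cyclic coordinate-wise Newton steps
    with finite-difference curvature, vectorized across subjects that share
    a sampling design.  Intended for covariate/correlation screening where
    thousands of replicate datasets must be processed; the SAEM fit provides
    the reference posterior-mean EBEs.
    """
    from . import _kernels

    subjects = (
        compile_dataset(dataset) if not isinstance(dataset, list) else dataset
    )
    P = len(model.parameters)
    idx = {p: i for i, p in enumerate(model.parameters)}
    ki = tuple(
        idx[p] if p in idx else -1
        for p in ("ka", "Tk0", "Fr", "V1", "V2", "Q", "CL", "F")
    )
    is_log = np.array(
        [model.transforms.get(p, "log") == "log" for p in model.parameters]
    )
    omega2 = np.array([max(model.omega2[p], 1e-8) for p in model.parameters])
    rows = []
    for sub in subjects:
        m = model.m_vector() + model.covariate_offsets(sub.covs.WT0)
        eta = np.zeros(P)
        occs = [
            (
                np.ascontiguousarray(o.times, dtype=np.float64),
                np.ascontiguousarray(o.ev_times, dtype=np.float64),
                np.ascontiguousarray(o.ev_amounts, dtype=np.float64),
                np.ascontiguousarray(o.ev_oral, dtype=np.bool_),
                np.ascontiguousarray(o.dv, dtype=np.float64),
                np.ascontiguousarray(o.blq, dtype=np.bool_),
                np.ascontiguousarray(o.lloq, dtype=np.float64),
            )
            for o in sub.occasions
        ]

        def neglogpost(e):
            tot = 0.5 * float(np.sum(e * e / omega2))
            psi = m + e
            phi = np.where(is_log, np.exp(psi), 1.0 / (1.0 + np.exp(-psi)))
            ika, itk, ifr, iv1, iv2, iq, icl, iF = ki
            for (t, evt, eva, evo, dv, blq, lloq) in occs:
                tot -= _kernels.occ_loglik(
                    phi[ika], phi[itk], phi[ifr], phi[iv1],
                    1.0 if iv2 < 0 else phi[iv2],
                    0.0 if iq < 0 else phi[iq],
                    phi[icl], phi[iF],
                    t, evt, eva, evo, dv, blq, lloq, model.b,
                )
            return tot

        f0 = neglogpost(eta)
        h = 0.05
        for _ in range(n_sweeps):
            moved = 0.0
            for j in range(P):
                e_plus = eta.copy(); e_plus[j] += h
                e_minus = eta.copy(); e_minus[j] -= h
                fp, fm = neglogpost(e_plus), neglogpost(e_minus)
                g = (fp - fm) / (2 * h)
                curv = (fp - 2 * f0 + fm) / (h * h)
                step = -g / curv if curv > 1e-9 else -np.sign(g) * h
                step = float(np.clip(step, -0.5, 0.5))
                if abs(step) < 1e-12:
                    continue
                trial = eta.copy(); trial[j] += step
                ft = neglogpost(trial)
                if ft < f0:
                    eta, f0 = trial, ft
                    moved += abs(step)
            if moved < tol:
                break
        row = {"ID": sub.sid, "WT0": sub.covs.WT0}
        row.update(dict(zip(model.parameters, eta.tolist())))
        rows.append(row)
    return pd.DataFrame(rows)


def run_diagnostics(
    dataset,
    fit,
    n_simulations: int = 500,
    seed: int = 0,
) -> DiagnosticsReport:
    """Full diagnostics for a FitResult: GOF pairs, IWRES, NPDE, screens."""
    subjects = (
        compile_dataset(dataset) if not isinstance(dataset, list) else dataset
    )
    model = fit.model
    ebes = fit.ebes.set_index(["ID", "OCC"])
    pairs, iwres_all = [], []
    for sub in subjects:
        for occ in sub.occasions:
            phi_row = ebes.loc[(sub.sid, occ.label)][list(model.parameters)]
            phi = phi_row.to_numpy(dtype=float)
            ipred = occasion_predictions(model, occ, phi)
            keep = ~occ.blq
            pairs.append(pd.DataFrame({
                "ID": sub.sid, "OCC": occ.label, "TIME": occ.times[keep],
                "DV": occ.dv[keep], "IPRED": ipred[keep],
            }))
            iwres_all.append(compute_iwres(occ.dv[keep], ipred[keep], model.b))
    obs_vs_pred = pd.concat(pairs, ignore_index=True)
    iwres = np.concatenate(iwres_all)
    npde, flags = compute_npde(subjects, model, max(n_simulations, 100), seed)
    eta_corr = eta_correlation_screen(fit.etas)
    covs = pd.DataFrame([
        {"ID": s.sid, "WT0": s.covs.WT0, "SEX": s.covs.sex, "FED": s.covs.fed}
        for s in subjects
    ])
    cov_table = covariate_screen(fit.etas, covs,
                                 reference_bodyweight=model.reference_bodyweight)
    bands = prediction_distribution(subjects, model, n_simulations, seed=seed + 1)
    return DiagnosticsReport(
        obs_vs_pred=obs_vs_pred,
        iwres=iwres,
        npde=npde,
        npde_flags=flags,
        eta_correlations=eta_corr,
        covariate_table=cov_table,
        bands=bands,
    )
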