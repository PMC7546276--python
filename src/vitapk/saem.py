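"""Stochastic approximation EM estimation of the population PK model.

The estimator alternates

* an E-like step: Metropolis-Hastings sampling of the individual
  transformed parameters, decomposed into subject-level deviations (eta,
  variance omega^2) and occasion-level deviations (kappa, variance gamma^2),
  targeting their conditional distribution given the data; and
* an M-like step: stochastic-approximation averaging of the complete-data
  sufficient statistics of the transformed individual parameters, followed by
  a generalized-least-squares update of the typical values (and the
  bodyweight coefficient on V1) and one EM step for the variance components.

The schedule has two phases: an exploratory phase with unit step size (and a
simulated-annealing constraint that keeps variances from collapsing early)
followed by a smoothing phase with step size (iter - K1)^(-a), a in (0.5, 1].
With few subjects the variance statistics are noisy, so several independent
MCMC chains are run per subject and their statistics averaged (by default
enough chains to bring subjects x chains to about 50, the convention of
mainstream SAEM implementations); an exploratory-phase cap on the variance
updates guards against transient excursions.

Posterior-mean individual estimates (EBEs) are accumulated over the
smoothing phase.  The marginal log-likelihood is estimated afterwards by
importance sampling from a Gaussian proposal built on the conditional draws,
and model comparison uses BIC = -2 loglik + P log(N subjects).

The proportional-error constant ``b`` is updated from the uncensored
weighted residuals of the current individual draws; censored (BLQ) records
inform the individual-parameter sampling through the M3 likelihood term but
are left out of the ``b`` update.

Everything is driven by one numpy Generator seeded from the configuration,
so a fit is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import _kernels
from .dataio import StudyDataset
from .population import (
    PARAM_ORDER,
    CompiledSubject,
    PopulationModel,
    compile_dataset,
    covariate_coding_value,
    occasion_predictions,
)

__all__ = [
    "SAEMConfig",
    "FitResult",
    "saem_fit",
    "saem_fit_best",
    "compute_bic",
    "compute_rse",
    "stabilize_random_effects",
    "mcmc_individual_step",
    "mh_update",
    "importance_sampling_loglik",
    "loglik_importance_sampling",
    "initial_estimates",
    "fd_hessian",
]


@dataclass(frozen=True)
class SAEMConfig:
    """Iteration schedule and Monte Carlo sizes of the SAEM run."""

    n_exploratory: int = 1000
    n_smoothing: int = 500
    n_chains: int | None = None        # None: ceil(50 / n_subjects), capped at 5
    mcmc_kernel_reps: int = 2
    step_size_exponent: float = 0.7
    seed: int = 0
    loglik_is_samples: int = 1000
    annealing_rate: float = 0.95
    variance_cap: float = 4.0          # exploratory-phase bound on omega2/gamma2
    fixed_inflation: float = 0.09      # early inflation of fixed variances (0 = off)
    stabilize_threshold: float = 1e-4  # SD below which a random effect is fixed
    stabilize_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_exploratory < 1 or self.n_smoothing < 1:
            raise ValueError("iteration counts must be positive")
        if not 0.5 < self.step_size_exponent <= 1.0:
            raise ValueError("step_size_exponent must lie in (0.5, 1]")
        if self.n_chains is not None and self.n_chains < 1:
            raise ValueError("n_chains must be positive")
        if self.mcmc_kernel_reps < 1:
            raise ValueError("mcmc_kernel_reps must be positive")

    def resolve_chains(self, n_subjects: int) -> int:
        if self.n_chains is not None:
            return self.n_chains
        return min(max(int(math.ceil(50.0 / max(n_subjects, 1))), 1), 5)


@dataclass
class FitResult:
    """Estimates, uncertainties, individual estimates and fit diagnostics."""

    model: PopulationModel                 # fitted population model
    loglik: float
    loglik_se: float
    bic: float
    n_params: int
    n_subjects: int
    ebes: pd.DataFrame                     # posterior-mean phi per subject/occasion
    etas: pd.DataFrame                     # posterior-mean eta per subject
    trajectories: pd.DataFrame             # parameter search paths per iteration
    converged: bool
    fixed_omega: set = field(default_factory=set)
    fixed_gamma: set = field(default_factory=set)
    rse: dict | None = None
    is_ess: float = float("nan")
    config: SAEMConfig | None = None
    proposal: dict | None = None           # per-subject IS proposal (mean, var)


def compute_bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """BIC = -2 loglik + P log(N), N = number of subjects."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return -2.0 * loglik + n_params * math.log(n_subjects)


def stabilize_random_effects(
    variances: dict, threshold: float = 1e-4, fix_sd: float = 0.1
) -> tuple[dict, set]:
    """Fix degenerate random effects at a nominal 10% CV.

    Any variance whose standard deviation estimate fell below ``threshold``
    is set to ``fix_sd**2`` and flagged for removal from estimation.
    """
    adjusted = dict(variances)
    fixed = set()
    for name, var in variances.items():
        if math.sqrt(max(var, 0.0)) < threshold:
            adjusted[name] = fix_sd ** 2
            fixed.add(name)
    return adjusted, fixed


# ---------------------------------------------------------------------------
# generic MCMC / importance-sampling primitives (also used by unit oracles)
# ---------------------------------------------------------------------------

def mh_update(
    x: float,
    logpost: Callable[[float], float],
    scale: float,
    rng: np.random.Generator,
    current_logpost: float | None = None,
):
    """One scalar Metropolis-Hastings random-walk update.

    Returns ``(x_new, logpost_new, accepted)``.  Non-finite proposals are
    rejected outright; a proposal equal to the current state is always
    accepted.
    """
    lp0 = logpost(x) if current_logpost is None else current_logpost
    prop = x + scale * rng.standard_normal()
    lp1 = logpost(prop)
    if not math.isfinite(lp1):
        return x, lp0, False
    if math.log(rng.random()) < lp1 - lp0:
        return prop, lp1, True
    return x, lp0, False


def importance_sampling_loglik(
    loglik_fn: Callable[[np.ndarray], np.ndarray],
    prior_var: np.ndarray,
    proposal_mean: np.ndarray,
    proposal_var: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    base_draws=None,
    df: float | None = 5.0,
):
    """Importance-sampling estimate of log integral p(y|z) p(z) dz.

    ``z`` has an independent centered Gaussian prior with variances
    ``prior_var``.  The proposal is centered at ``proposal_mean`` with scale
    ``proposal_var`` (a variance vector or a full covariance matrix capturing
    the posterior correlations); with ``df`` set it is a multivariate
    Student-t with that many degrees of freedom, whose heavier tails protect
    the effective sample size in high-dimensional latent spaces, otherwise
    Gaussian.  ``loglik_fn`` maps an (S, D) matrix of draws to an (S,) vector
    of conditional log-likelihoods.  ``base_draws`` (a ``(z, u)`` pair of
    standard-normal and chi-square innovations) fixes the randomness for
    common-random-number evaluations.  Returns
    ``(loglik, mc_se_of_log, ess)``.
    """
    prior_var = np.asarray(prior_var, dtype=float)
    proposal_mean = np.asarray(proposal_mean, dtype=float)
    proposal_var = np.asarray(proposal_var, dtype=float)
    D = prior_var.size
    if D == 0:
        ll = float(loglik_fn(np.zeros((1, 0)))[0])
        return ll, 0.0, float(n_samples)
    if base_draws is not None:
        z, u = base_draws
    else:
        z = rng.standard_normal((n_samples, D))
        u = rng.chisquare(df, n_samples) / df if df else None
    if proposal_var.ndim == 2:
        cov = proposal_var + 1e-10 * np.eye(D)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            L = np.diag(np.sqrt(np.maximum(np.diag(cov), 1e-12)))
        log_det = 2.0 * float(np.sum(np.log(np.diag(L))))
        std = z @ L.T
    else:
        pv = np.maximum(proposal_var, 1e-12)
        log_det = float(np.sum(np.log(pv)))
        std = np.sqrt(pv) * z
    m2 = np.sum(z * z, axis=1)
    if df:
        scale = 1.0 / np.sqrt(u)
        draws = proposal_mean + std * scale[:, None]
        # mahalanobis distance of the t draw is m2/u
        log_q = (
            math.lgamma(0.5 * (df + D)) - math.lgamma(0.5 * df)
            - 0.5 * D * math.log(df * math.pi) - 0.5 * log_det
            - 0.5 * (df + D) * np.log1p(m2 / (df * u))
        )
    else:
        draws = proposal_mean + std
        log_q = -0.5 * (m2 + log_det + D * math.log(2.0 * math.pi))
    log_prior = -0.5 * np.sum(
        draws * draws / prior_var + np.log(2.0 * math.pi * prior_var), axis=1
    )
    log_w = loglik_fn(draws) + log_prior - log_q
    log_w = np.where(np.isfinite(log_w), log_w, -np.inf)
    lse = float(logsumexp(log_w))
    loglik = lse - math.log(n_samples)
    w = np.exp(log_w - lse)          # normalized weights
    sum_w2 = float(np.sum(w * w))
    ess = 1.0 / sum_w2 if sum_w2 > 0 else 0.0
    # delta-method SE of the log of a mean of weights
    mc_se = math.sqrt(max(sum_w2 - 1.0 / n_samples, 0.0))
    return loglik, mc_se, ess


def fd_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 0.01):
    """Central finite-difference Hessian of a smooth scalar function."""
    x = np.asarray(x, dtype=float)
    d = x.size
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        H[i, i] = (f(x + e) - 2.0 * f0 + f(x - e)) / h ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h * h)
    return H


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------

class _OccData:
    """Per-occasion arrays in the layout the fast kernels expect."""

    __slots__ = (
        "label", "times", "dv", "blq", "lloq",
        "ev_times", "ev_amounts", "ev_oral", "active", "n_obs",
    )

    def __init__(self, occ, active_mask):
        self.label = occ.label
        self.times = np.ascontiguousarray(occ.times, dtype=np.float64)
        self.dv = np.ascontiguousarray(occ.dv, dtype=np.float64)
        self.blq = np.ascontiguousarray(occ.blq, dtype=np.bool_)
        self.lloq = np.ascontiguousarray(occ.lloq, dtype=np.float64)
        self.ev_times = np.ascontiguousarray(occ.ev_times, dtype=np.float64)
        self.ev_amounts = np.ascontiguousarray(occ.ev_amounts, dtype=np.float64)
        self.ev_oral = np.ascontiguousarray(occ.ev_oral, dtype=np.bool_)
        self.active = active_mask
        self.n_obs = int(self.times.size)


class _SubjectState:
    __slots__ = ("sid", "x", "wt0", "occs", "n_occ", "eta", "kappa", "occ_ll")

    def __init__(self, sid, x, wt0, occs, P, C):
        self.sid = sid
        self.x = x           # covariate coding value c(WT0)
        self.wt0 = wt0
        self.occs = occs
        self.n_occ = len(occs)
        self.eta = np.zeros((C, P))
        self.kappa = np.zeros((C, P, self.n_occ))
        self.occ_ll = np.zeros((C, self.n_occ))


class _Engine:
    def __init__(
        self,
        subjects: Sequence[CompiledSubject],
        model: PopulationModel,
        config: SAEMConfig,
        estimate_covariate: bool,
    ):
        self.cfg = config
        self.model = model
        self.params = model.parameters
        self.P = len(self.params)
        self.idx = {p: i for i, p in enumerate(self.params)}
        self.transform_is_log = np.array(
            [model.transforms.get(p, "log") == "log" for p in self.params]
        )
        self.iV1 = self.idx["V1"]
        self.one_cpt = "Q" not in self.idx
        self._ki = tuple(
            self.idx[p] if p in self.idx else -1
            for p in ("ka", "Tk0", "Fr", "V1", "V2", "Q", "CL", "F")
        )
        self.estimate_covariate = estimate_covariate
        self.fixed_omega: set = set()
        self.fixed_gamma: set = set()

        self.subs = []
        for sub in subjects:
            x = covariate_coding_value(
                sub.covs.WT0, model.reference_bodyweight, model.covariate_coding
            )
            occs = [_OccData(o, self._active_mask(o)) for o in sub.occasions]
            self.subs.append(None)  # placeholder replaced below
            self.subs[-1] = (sub.sid, x, sub.covs.WT0, occs)
        self.N = len(self.subs)
        self.C = config.resolve_chains(self.N)
        self.subs = [
            _SubjectState(sid, x, wt0, occs, self.P, self.C)
            for (sid, x, wt0, occs) in self.subs
        ]
        self.n_occ_total = sum(s.n_occ for s in self.subs)

        # parameter state (transformed scale)
        self.m = model.m_vector()
        self.beta = model.beta_V1_WT0
        self.b = model.b
        self.omega2 = np.array([model.omega2[p] for p in self.params])
        self.gamma2 = np.array([model.gamma2[p] for p in self.params])
        self.iiv_free = self.omega2 > 0
        self.iov_free = self.gamma2 > 0

        # proposal scales and acceptance bookkeeping
        self.scale_eta = np.full(self.P, 0.4)
        self.scale_kappa = np.full(self.P, 0.4)
        self.acc_eta = np.zeros(self.P)
        self.try_eta = np.zeros(self.P)
        self.acc_kappa = np.zeros(self.P)
        self.try_kappa = np.zeros(self.P)

        # SA sufficient statistics
        self.S = np.zeros((self.N, self.P))
        self.Qs = np.zeros((self.N, self.P))
        self.U = np.zeros((self.N, self.P))
        self.Tb = 0.0
        self.n_unc = sum(int((~o.blq).sum()) for s in self.subs for o in s.occs)

        # EBE accumulators (smoothing phase; each chain draw is one sample)
        self.psi_mean = [np.zeros((self.P, s.n_occ)) for s in self.subs]
        self.lat_mean = [np.zeros(self.P * (1 + s.n_occ)) for s in self.subs]
        # full covariance of the latent draws, for the IS proposal
        self.lat_m2 = [
            np.zeros((self.P * (1 + s.n_occ), self.P * (1 + s.n_occ)))
            for s in self.subs
        ]
        self.n_ebe = 0

        self.traj = []

    # -- helpers ---------------------------------------------------------------
    def _active_mask(self, occ) -> np.ndarray:
        mask = np.zeros(len(self.params), dtype=bool)
        for p in ("V1", "V2", "Q", "CL"):
            if p in self.idx:
                mask[self.idx[p]] = True
        if occ.ev_oral.any():
            for p in ("ka", "Tk0", "Fr", "F"):
                if p in self.idx:
                    mask[self.idx[p]] = True
        return mask

    def m_tilde(self, sub: _SubjectState) -> np.ndarray:
        m = self.m.copy()
        m[self.iV1] += self.beta * sub.x
        return m

    def phi(self, psi: np.ndarray) -> np.ndarray:
        out = np.where(self.transform_is_log, np.exp(psi), 0.0)
        logit_dims = ~self.transform_is_log
        if logit_dims.any():
            out[logit_dims] = 1.0 / (1.0 + np.exp(-psi[logit_dims]))
        return out

    def occ_ll_value(self, phi: np.ndarray, occ: _OccData) -> float:
        ika, itk, ifr, iv1, iv2, iq, icl, iF = self._ki
        return _kernels.occ_loglik(
            phi[ika], phi[itk], phi[ifr], phi[iv1],
            1.0 if iv2 < 0 else phi[iv2],
            0.0 if iq < 0 else phi[iq],
            phi[icl], phi[iF],
            occ.times, occ.ev_times, occ.ev_amounts, occ.ev_oral,
            occ.dv, occ.blq, occ.lloq, self.b,
        )

    def occ_pred_value(self, phi: np.ndarray, occ: _OccData) -> np.ndarray:
        ika, itk, ifr, iv1, iv2, iq, icl, iF = self._ki
        return _kernels.occ_conc(
            phi[ika], phi[itk], phi[ifr], phi[iv1],
            1.0 if iv2 < 0 else phi[iv2],
            0.0 if iq < 0 else phi[iq],
            phi[icl], phi[iF],
            occ.times, occ.ev_times, occ.ev_amounts, occ.ev_oral,
        )

    def refresh_loglik(self):
        for sub in self.subs:
            m_t = self.m_tilde(sub)
            for c in range(self.C):
                for o in range(sub.n_occ):
                    psi = m_t + sub.eta[c] + sub.kappa[c, :, o]
                    sub.occ_ll[c, o] = self.occ_ll_value(self.phi(psi), sub.occs[o])

    # -- MCMC ------------------------------------------------------------------
    def sweep_subject(self, sub: _SubjectState, rng):
        m_t = self.m_tilde(sub)
        iiv_dims = np.flatnonzero(self.iiv_free)
        iov_dims = np.flatnonzero(self.iov_free)
        for c in range(self.C):
            eta = sub.eta[c]
            kappa = sub.kappa[c]
            occ_ll = sub.occ_ll[c]
            for _ in range(self.cfg.mcmc_kernel_reps):
                for p in iiv_dims:
                    old = eta[p]
                    new = old + self.scale_eta[p] * rng.standard_normal()
                    dlp = -0.5 * (new * new - old * old) / self.omega2[p]
                    eta[p] = new
                    delta = dlp
                    new_ll = []
                    for o in range(sub.n_occ):
                        if not sub.occs[o].active[p]:
                            continue
                        psi = m_t + eta + kappa[:, o]
                        ll = self.occ_ll_value(self.phi(psi), sub.occs[o])
                        new_ll.append((o, ll))
                        delta += ll - occ_ll[o]
                    self.try_eta[p] += 1
                    if math.isfinite(delta) and math.log(rng.random()) < delta:
                        for (o, ll) in new_ll:
                            occ_ll[o] = ll
                        self.acc_eta[p] += 1
                    else:
                        eta[p] = old
                for o in range(sub.n_occ):
                    occ = sub.occs[o]
                    for p in iov_dims:
                        if not occ.active[p]:
                            # data-free component: exact draw from its prior
                            kappa[p, o] = math.sqrt(self.gamma2[p]) * rng.standard_normal()
                            continue
                        old = kappa[p, o]
                        new = old + self.scale_kappa[p] * rng.standard_normal()
                        dlp = -0.5 * (new * new - old * old) / self.gamma2[p]
                        kappa[p, o] = new
                        psi = m_t + eta + kappa[:, o]
                        ll_new = self.occ_ll_value(self.phi(psi), occ)
                        self.try_kappa[p] += 1
                        if math.isfinite(ll_new) and math.log(rng.random()) < dlp + ll_new - occ_ll[o]:
                            occ_ll[o] = ll_new
                            self.acc_kappa[p] += 1
                        else:
                            kappa[p, o] = old

    def adapt_scales(self):
        for arr_acc, arr_try, scales in (
            (self.acc_eta, self.try_eta, self.scale_eta),
            (self.acc_kappa, self.try_kappa, self.scale_kappa),
        ):
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(arr_try > 0, arr_acc / np.maximum(arr_try, 1), 0.3)
            scales *= np.exp(0.4 * (rate - 0.3))
            np.clip(scales, 1e-3, 5.0, out=scales)
            arr_acc[:] = 0
            arr_try[:] = 0

    # -- statistics and M-step ---------------------------------------------------
    def accumulate(self, step: float):
        Tb_now = 0.0
        inv_C = 1.0 / self.C
        for i, sub in enumerate(self.subs):
            m_t = self.m_tilde(sub)
            s_acc = np.zeros(self.P)
            q_acc = np.zeros(self.P)
            u_acc = np.zeros(self.P)
            for c in range(self.C):
                psi = m_t[:, None] + sub.eta[c][:, None] + sub.kappa[c]  # (P, n_occ)
                s = psi.sum(axis=1)
                s_acc += s
                q_acc += (psi * psi).sum(axis=1)
                u_acc += s * s
                for o in range(sub.n_occ):
                    occ = sub.occs[o]
                    u = ~occ.blq
                    if not u.any():
                        continue
                    pred = self.occ_pred_value(self.phi(psi[:, o]), occ)
                    z = (occ.dv[u] - pred[u]) / np.maximum(pred[u], 1e-12)
                    Tb_now += inv_C * float(np.sum(z * z))
            self.S[i] += step * (inv_C * s_acc - self.S[i])
            self.Qs[i] += step * (inv_C * q_acc - self.Qs[i])
            self.U[i] += step * (inv_C * u_acc - self.U[i])
        self.Tb += step * (Tb_now - self.Tb)

    def accumulate_ebes(self):
        for c in range(self.C):
            self.n_ebe += 1
            k = self.n_ebe
            for i, sub in enumerate(self.subs):
                m_t = self.m_tilde(sub)
                psi = m_t[:, None] + sub.eta[c][:, None] + sub.kappa[c]
                self.psi_mean[i] += (psi - self.psi_mean[i]) / k
                lat = np.concatenate([sub.eta[c], sub.kappa[c].ravel()])
                d = lat - self.lat_mean[i]
                self.lat_mean[i] += d / k
                self.lat_m2[i] += np.outer(d, lat - self.lat_mean[i])

    def m_step(self, annealed: bool):
        n_i = np.array([s.n_occ for s in self.subs], dtype=float)
        x = np.array([s.x for s in self.subs])
        psi_bar = self.S / n_i[:, None]

        for p in range(self.P):
            v = np.maximum(self.omega2[p] + self.gamma2[p] / n_i, 1e-12)
            w_gls = 1.0 / v
            if p == self.iV1 and self.estimate_covariate:
                X = np.column_stack([np.ones(self.N), x])
                WX = X * w_gls[:, None]
                coef = np.linalg.solve(X.T @ WX, WX.T @ psi_bar[:, p])
                self.m[p], self.beta = float(coef[0]), float(coef[1])
            else:
                self.m[p] = float(np.sum(w_gls * psi_bar[:, p]) / np.sum(w_gls))

        # one EM step for the variance components
        for p in range(self.P):
            m_t = self.m[p] + (self.beta * x if p == self.iV1 else 0.0)
            S, Q, U = self.S[:, p], self.Qs[:, p], self.U[:, p]
            om2, ga2 = self.omega2[p], self.gamma2[p]
            free_om = self.iiv_free[p] and self.params[p] not in self.fixed_omega
            free_ga = self.iov_free[p] and self.params[p] not in self.fixed_gamma
            if self.iiv_free[p]:
                denom = np.maximum(ga2 + n_i * om2, 1e-300)
                w = n_i * om2 / denom
                v_eta = om2 * ga2 / denom
            else:
                w = np.zeros(self.N)
                v_eta = np.zeros(self.N)
            dev2 = U / n_i ** 2 - 2.0 * m_t * S / n_i + m_t ** 2
            eta2 = w ** 2 * dev2 + v_eta
            if free_om:
                new_om = float(np.mean(eta2))
                if annealed:
                    new_om = min(
                        max(new_om, self.cfg.annealing_rate * om2),
                        self.cfg.variance_cap,
                    )
                self.omega2[p] = max(new_om, 1e-12)
            if free_ga:
                ssq = Q - 2.0 * m_t * S + n_i * m_t ** 2
                cross = (w / n_i) * (U - 2.0 * n_i * m_t * S + n_i ** 2 * m_t ** 2)
                e_kap2 = ssq - 2.0 * cross + n_i * eta2
                new_ga = float(np.sum(np.maximum(e_kap2, 0.0)) / np.sum(n_i))
                if annealed:
                    new_ga = min(
                        max(new_ga, self.cfg.annealing_rate * ga2),
                        self.cfg.variance_cap,
                    )
                self.gamma2[p] = max(new_ga, 1e-12)

        if self.n_unc > 0:
            new_b = math.sqrt(max(self.Tb / self.n_unc, 1e-12))
            if annealed:
                new_b = max(new_b, self.cfg.annealing_rate * self.b)
            self.b = max(new_b, 1e-4)

    def recenter(self, m_old: np.ndarray, beta_old: float):
        """Shift eta so each chain's psi is unchanged by the fixed-effect update."""
        for sub in self.subs:
            shift = m_old - self.m
            shift[self.iV1] += (beta_old - self.beta) * sub.x
            sub.eta += shift[None, :]

    def record(self, iteration: int, phase: str):
        row = {"iteration": iteration, "phase": phase, "b": self.b,
               "beta_V1_WT0": self.beta}
        mu = self.natural_mu()
        for p, name in enumerate(self.params):
            row[name] = mu[name]
            row[f"omega2_{name}"] = self.omega2[p]
            row[f"gamma2_{name}"] = self.gamma2[p]
        self.traj.append(row)

    def natural_mu(self) -> dict:
        out = {}
        for p, name in enumerate(self.params):
            out[name] = (
                math.exp(self.m[p])
                if self.transform_is_log[p]
                else 1.0 / (1.0 + math.exp(-self.m[p]))
            )
        return out


def _steps(cfg: SAEMConfig):
    for k in range(1, cfg.n_exploratory + cfg.n_smoothing + 1):
        if k <= cfg.n_exploratory:
            yield k, 1.0, "exploratory"
        else:
            yield k, (k - cfg.n_exploratory) ** (-cfg.step_size_exponent), "smoothing"


def saem_fit(
    dataset: StudyDataset | Sequence[CompiledSubject],
    config: SAEMConfig,
    init: PopulationModel | None = None,
    estimate_covariate: bool = True,
    compute_loglik: bool = True,
    fix_variances: bool = False,
) -> FitResult:
    """Fit the population model to a dataset by SAEM.

    ``init`` provides the model structure (parameter set, transforms,
    covariate coding) and starting values; when omitted, starting values come
    from `initial_estimates` heuristics with 0.1 starting variances.  With
    ``fix_variances`` the random-effect variances are held at their ``init``
    values and removed from estimation (the treatment the original analysis
    applied to its degenerate random effects), so the search covers the fixed
    effects and the error constant only.  The fit is deterministic for a
    fixed ``config.seed``.
    """
    subjects = (
        compile_dataset(dataset) if isinstance(dataset, StudyDataset) else list(dataset)
    )
    if not subjects:
        raise ValueError("dataset has no subjects")
    for sub in subjects:
        if not any(o.n_obs for o in sub.occasions):
            raise ValueError(f"subject {sub.sid} has no observations")
    if init is None:
        init = initial_estimates(subjects)
    rng = np.random.default_rng(config.seed)

    eng = _Engine(subjects, init, config, estimate_covariate)
    if fix_variances:
        eng.fixed_omega = set(init.parameters)
        eng.fixed_gamma = set(init.parameters)
    # fixed variances are inflated early and annealed down to their targets,
    # so the fixed-effect search can move fast before consolidating
    omega2_target = eng.omega2.copy()
    gamma2_target = eng.gamma2.copy()
    inflate = config.fixed_inflation * np.ones(eng.P)
    eng.refresh_loglik()

    for k, step, phase in _steps(config):
        annealed = phase == "exploratory"
        if annealed and (eng.fixed_omega or eng.fixed_gamma):
            lvl = inflate * config.annealing_rate ** k
            for j, p in enumerate(eng.params):
                if p in eng.fixed_omega and eng.iiv_free[j]:
                    eng.omega2[j] = max(omega2_target[j], lvl[j])
                if p in eng.fixed_gamma and eng.iov_free[j]:
                    eng.gamma2[j] = max(gamma2_target[j], lvl[j])
        for sub in eng.subs:
            eng.sweep_subject(sub, rng)
        if annealed and k % 5 == 0:
            eng.adapt_scales()
        eng.accumulate(step)
        m_old, beta_old = eng.m.copy(), eng.beta
        eng.m_step(annealed)
        eng.recenter(m_old, beta_old)
        if phase == "smoothing":
            eng.accumulate_ebes()
        eng.record(k, phase)
        if k == config.n_exploratory:
            # degenerate random effects: fix at nominal 10% CV, drop from search
            om, fixed_o = stabilize_random_effects(
                dict(zip(eng.params, eng.omega2)),
                config.stabilize_threshold, config.stabilize_sd,
            )
            ga, fixed_g = stabilize_random_effects(
                dict(zip(eng.params, eng.gamma2)),
                config.stabilize_threshold, config.stabilize_sd,
            )
            eng.omega2 = np.array([om[p] for p in eng.params])
            eng.gamma2 = np.array([ga[p] for p in eng.params])
            eng.fixed_omega |= fixed_o
            eng.fixed_gamma |= fixed_g
            eng.refresh_loglik()

    traj = pd.DataFrame(eng.traj)
    tail = traj[traj["phase"] == "smoothing"].tail(min(50, config.n_smoothing))
    converged = True
    for name in list(eng.params) + ["b"]:
        vals = tail[name].to_numpy()
        ref = max(abs(vals[-1]), 1e-12)
        if np.max(np.abs(vals - vals[-1])) / ref > 0.01:
            converged = False

    fitted = init.with_updates(
        mu=eng.natural_mu(),
        beta_V1_WT0=eng.beta if estimate_covariate else init.beta_V1_WT0,
        b=eng.b,
        omega2=dict(zip(eng.params, eng.omega2.tolist())),
        gamma2=dict(zip(eng.params, eng.gamma2.tolist())),
    )

    # EBEs: posterior-mean phi per subject/occasion, posterior-mean eta
    ebe_rows, eta_rows, proposal = [], [], {}
    for i, sub in enumerate(eng.subs):
        for o in range(sub.n_occ):
            row = {"ID": sub.sid, "OCC": sub.occs[o].label}
            phi_o = eng.phi(eng.psi_mean[i][:, o])
            row.update({p: phi_o[j] for j, p in enumerate(eng.params)})
            ebe_rows.append(row)
        lat_mean = eng.lat_mean[i]
        lat_var = eng.lat_m2[i] / max(eng.n_ebe - 1, 1)
        proposal[sub.sid] = (lat_mean, lat_var)
        erow = {"ID": sub.sid, "WT0": sub.wt0}
        erow.update({p: lat_mean[j] for j, p in enumerate(eng.params)})
        eta_rows.append(erow)
    ebes = pd.DataFrame(ebe_rows)
    etas = pd.DataFrame(eta_rows)

    n_fixed_effects = len(eng.params) + (1 if estimate_covariate else 0)
    n_var = int(
        sum(1 for j, p in enumerate(eng.params)
            if eng.iiv_free[j] and p not in eng.fixed_omega)
        + sum(1 for j, p in enumerate(eng.params)
              if eng.iov_free[j] and p not in eng.fixed_gamma)
    )
    n_params = n_fixed_effects + n_var + 1  # + residual-error constant

    result = FitResult(
        model=fitted,
        loglik=float("nan"),
        loglik_se=float("nan"),
        bic=float("nan"),
        n_params=n_params,
        n_subjects=eng.N,
        ebes=ebes,
        etas=etas,
        trajectories=traj,
        converged=converged,
        fixed_omega=eng.fixed_omega,
        fixed_gamma=eng.fixed_gamma,
        config=config,
        proposal=proposal,
    )
    if compute_loglik:
        ll, se, ess = loglik_importance_sampling(
            subjects, result, config.loglik_is_samples,
            rng=np.random.default_rng(config.seed + 104729),
        )
        result.loglik = ll
        result.loglik_se = se
        result.is_ess = ess
        result.bic = compute_bic(ll, n_params, eng.N)
    return result


# ---------------------------------------------------------------------------
# marginal likelihood, standard errors, single-step API
# ---------------------------------------------------------------------------

def _subject_latent_layout(model: PopulationModel, sub: CompiledSubject):
    """Free latent dimensions for one subject: eta dims then kappa blocks."""
    omega2 = np.array([model.omega2[p] for p in model.parameters])
    gamma2 = np.array([model.gamma2[p] for p in model.parameters])
    n_occ = len(sub.occasions)
    eta_dims = np.flatnonzero(omega2 > 0)
    kap_dims = np.flatnonzero(gamma2 > 0)
    parts = [omega2[eta_dims]] + [gamma2[kap_dims]] * n_occ
    prior_var = np.concatenate(parts) if parts else np.zeros(0)
    return eta_dims, kap_dims, prior_var


def _subject_loglik_fn(model: PopulationModel, sub: CompiledSubject, b=None):
    """(S, D) latent draws -> (S,) conditional log-likelihoods."""
    from .population import loglik_terms

    P = len(model.parameters)
    eta_dims, kap_dims, _ = _subject_latent_layout(model, sub)
    m = model.m_vector() + model.covariate_offsets(sub.covs.WT0)
    n_eta = eta_dims.size
    n_kap = kap_dims.size
    b_use = model.b if b is None else b

    def fn(draws: np.ndarray) -> np.ndarray:
        S = draws.shape[0]
        total = np.zeros(S)
        eta = np.zeros((S, P))
        if n_eta:
            eta[:, eta_dims] = draws[:, :n_eta]
        for o, occ in enumerate(sub.occasions):
            kap = np.zeros((S, P))
            if n_kap:
                kap[:, kap_dims] = draws[:, n_eta + o * n_kap: n_eta + (o + 1) * n_kap]
            phi = model.phi_from_psi(m + eta + kap)
            pred = occasion_predictions(model, occ, phi)
            ll = loglik_terms(occ.dv, pred, occ.blq, occ.lloq, b_use)
            total += ll.sum(axis=1)
        return total

    return fn


def _proposal_moments(proposal, model, sub, eta_dims, kap_dims):
    """Map stored latent means/variances onto the free-dimension layout.

    Stored layout is [eta (all P)] + [kappa.ravel() in (P, n_occ) order];
    the IS draw layout is [free eta dims] + per-occasion blocks of free
    kappa dims.  Returns the proposal mean and a full covariance inflated 2x.
    """
    lat_mean, lat_cov = proposal
    P = len(model.parameters)
    n_occ = len(sub.occasions)
    sel_parts = [eta_dims]
    for o in range(n_occ):
        sel_parts.append(P + kap_dims * n_occ + o)
    sel = np.concatenate(sel_parts).astype(int) if sel_parts else np.zeros(0, int)
    mean = lat_mean[sel]
    cov = 2.0 * lat_cov[np.ix_(sel, sel)]
    d = np.arange(sel.size)
    cov[d, d] = np.maximum(cov[d, d], 1e-8)
    return mean, cov


def loglik_importance_sampling(
    dataset: StudyDataset | Sequence[CompiledSubject],
    fit: FitResult,
    n_samples: int,
    rng: np.random.Generator | int | None = None,
):
    """Marginal log-likelihood by per-subject importance sampling.

    The proposal is an independent Gaussian per free latent dimension built
    on the conditional mean/variance recorded during the smoothing phase
    (variances inflated 2x); with no free random effects the integral is
    trivial and the conditional likelihood is returned exactly.  Returns
    ``(loglik, total mc standard error, min effective sample size)``.
    """
    subjects = (
        compile_dataset(dataset) if isinstance(dataset, StudyDataset) else list(dataset)
    )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    model = fit.model
    total, var_sum, min_ess = 0.0, 0.0, float("inf")
    for sub in subjects:
        eta_dims, kap_dims, prior_var = _subject_latent_layout(model, sub)
        D = prior_var.size
        fn = _subject_loglik_fn(model, sub)
        if D == 0:
            total += float(fn(np.zeros((1, 0)))[0])
            continue
        mean = np.zeros(D)
        var = prior_var.copy()
        if fit.proposal and sub.sid in fit.proposal:
            mean, var = _proposal_moments(
                fit.proposal[sub.sid], model, sub, eta_dims, kap_dims
            )
        ll, se, ess = importance_sampling_loglik(
            fn, prior_var, mean, var, n_samples, rng
        )
        total += ll
        var_sum += se ** 2
        min_ess = min(min_ess, ess)
    return total, math.sqrt(var_sum), min_ess


def compute_rse(
    fit: FitResult,
    dataset: StudyDataset | Sequence[CompiledSubject],
    n_samples: int = 300,
    step: float = 0.02,
    seed: int = 0,
) -> dict:
    """RSE% of the fixed effects and the error constant b.

    The observed information is approximated by a central finite-difference
    Hessian of the importance-sampling log-likelihood evaluated with common
    random numbers (fixed base draws), holding the variance components at
    their estimates.  Standard errors are mapped to the natural scale by the
    delta method; parameters whose information is not positive are reported
    as NaN.
    """
    subjects = (
        compile_dataset(dataset) if isinstance(dataset, StudyDataset) else list(dataset)
    )
    model = fit.model
    params = model.parameters
    names = list(params) + (["beta_V1_WT0"] if model.beta_V1_WT0 != 0.0 else []) + ["b"]
    rng = np.random.default_rng(seed)

    cache = []
    for sub in subjects:
        eta_dims, kap_dims, prior_var = _subject_latent_layout(model, sub)
        D = prior_var.size
        mean = np.zeros(D)
        var = prior_var.copy()
        if fit.proposal and sub.sid in fit.proposal:
            mean, var = _proposal_moments(
                fit.proposal[sub.sid], model, sub, eta_dims, kap_dims
            )
        base = (
            (rng.standard_normal((n_samples, D)), rng.chisquare(5.0, n_samples) / 5.0)
            if D else None
        )
        cache.append((sub, prior_var, mean, var, base))

    def loglik_at(theta: np.ndarray) -> float:
        mu = {}
        for i, p in enumerate(params):
            mu[p] = (
                math.exp(theta[i])
                if model.transforms.get(p, "log") == "log"
                else 1.0 / (1.0 + math.exp(-theta[i]))
            )
        j = len(params)
        beta = model.beta_V1_WT0
        if "beta_V1_WT0" in names:
            beta = theta[j]
            j += 1
        b = math.exp(theta[j])
        trial = model.with_updates(mu=mu, beta_V1_WT0=beta, b=b)
        total = 0.0
        for (sub, prior_var, mean, var, base) in cache:
            fn = _subject_loglik_fn(trial, sub)
            if prior_var.size == 0:
                total += float(fn(np.zeros((1, 0)))[0])
                continue
            ll, _, _ = importance_sampling_loglik(
                fn, prior_var, mean, var, base[0].shape[0], rng, base_draws=base
            )
            total += ll
        return total

    theta0 = list(model.m_vector())
    if "beta_V1_WT0" in names:
        theta0.append(model.beta_V1_WT0)
    theta0.append(math.log(model.b))
    theta0 = np.asarray(theta0)

    H = fd_hessian(loglik_at, theta0, h=step)
    rse = {}
    try:
        cov = np.linalg.inv(-H)
        diag = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        diag = np.full(theta0.size, np.nan)
    for i, name in enumerate(names):
        v = diag[i]
        if not np.isfinite(v) or v <= 0:
            rse[name] = float("nan")
            continue
        se_t = math.sqrt(v)
        if name == "beta_V1_WT0":
            est, se = model.beta_V1_WT0, se_t
        elif name == "b":
            est, se = model.b, model.b * se_t
        else:
            est = model.mu[name]
            if model.transforms.get(name, "log") == "log":
                se = est * se_t
            else:
                se = est * (1.0 - est) * se_t
        rse[name] = 100.0 * se / abs(est) if est != 0 else float("nan")
    return rse


def posterior_mean_etas(
    dataset,
    model: PopulationModel,
    n_iter: int = 200,
    burn: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior-mean subject-level etas under a fixed population model.

    Runs the MH kernel over the full (eta, kappa) decomposition with the
    population parameters frozen and averages the post-burn-in eta draws.
    This keeps occasion-level variability out of the subject-level estimates
    (unlike a mode search with the occasion effects collapsed) and is the
    estimator used for covariate and correlation screening when no full
    SAEM fit is at hand.
    """
    subjects = (
        compile_dataset(dataset) if isinstance(dataset, StudyDataset) else list(dataset)
    )
    cfg = SAEMConfig(
        n_exploratory=1, n_smoothing=1, n_chains=1, mcmc_kernel_reps=1, seed=seed
    )
    eng = _Engine(subjects, model, cfg, estimate_covariate=False)
    eng.refresh_loglik()
    rng = np.random.default_rng(seed)
    acc = np.zeros((eng.N, eng.P))
    count = 0
    for k in range(n_iter):
        for sub in eng.subs:
            eng.sweep_subject(sub, rng)
        if k % 5 == 4:
            eng.adapt_scales()
        if k >= burn:
            count += 1
            for i, sub in enumerate(eng.subs):
                acc[i] += sub.eta[0]
    acc /= max(count, 1)
    rows = []
    for i, sub in enumerate(eng.subs):
        row = {"ID": sub.sid, "WT0": sub.wt0}
        row.update(dict(zip(eng.params, acc[i].tolist())))
        rows.append(row)
    return pd.DataFrame(rows)


def mcmc_individual_step(
    subject: CompiledSubject,
    realization,
    model: PopulationModel,
    rng: np.random.Generator,
    scale: float = 0.4,
    reps: int = 1,
):
    """One MH kernel sweep for a single subject, for stepwise use.

    ``realization`` is ``(eta, kappa)`` with eta shape (P,) and kappa shape
    (P, n_occ) on the transformed scale; updated copies are returned along
    with the per-occasion conditional log-likelihoods.
    """
    cfg = SAEMConfig(
        n_exploratory=1, n_smoothing=1, n_chains=1, mcmc_kernel_reps=reps, seed=0
    )
    eng = _Engine([subject], model, cfg, estimate_covariate=False)
    sub = eng.subs[0]
    eta, kappa = realization
    sub.eta[0] = np.asarray(eta, dtype=float)
    sub.kappa[0] = np.asarray(kappa, dtype=float)
    eng.refresh_loglik()
    eng.scale_eta[:] = scale
    eng.scale_kappa[:] = scale
    eng.sweep_subject(sub, rng)
    return sub.eta[0].copy(), sub.kappa[0].copy(), sub.occ_ll[0].copy()


# ---------------------------------------------------------------------------
# initialization heuristics
# ---------------------------------------------------------------------------

def initial_estimates(
    subjects: Sequence[CompiledSubject],
    parameters: tuple = PARAM_ORDER,
    pooled_refine: bool = True,
) -> PopulationModel:
    """Starting values from the data: stripping, AUC ratios, pooled NLS.

    Intravenous occasions provide a biexponential strip for the disposition
    parameters; the oral/IV dose-normalized AUC ratio initializes
    bioavailability; the oral peak time initializes the absorption timing.
    A naive pooled fit (nonlinear least squares on the dose-normalized log
    concentrations of all single-dose curves, IV first, then oral) then
    refines these crude values.  All stages fall back to mild defaults when
    the required data are absent.  Starting variances are 0.1 and b starts
    at 0.3.
    """
    iv_curves, po_curves = [], []
    for sub in subjects:
        for occ in sub.occasions:
            if occ.ev_times.size != 1:
                continue
            dose = float(occ.ev_amounts.sum())
            u = ~occ.blq
            if u.sum() < 4 or dose <= 0:
                continue
            rec = (occ.times[u], occ.dv[u], dose)
            (po_curves if occ.ev_oral.any() else iv_curves).append(rec)

    CL = V1 = Q = V2 = None
    if iv_curves:
        try:
            CL, V1, Q, V2 = _strip_iv(iv_curves)
        except Exception:
            pass
    auc_iv = np.mean([_auc(t, c) / d for (t, c, d) in iv_curves]) if iv_curves else None
    auc_po = np.mean([_auc(t, c) / d for (t, c, d) in po_curves]) if po_curves else None

    if CL is None and auc_iv:
        CL = 1.0 / auc_iv
    if CL is None and auc_po:
        CL = 0.5 / auc_po  # assume F ~ 0.5 when no IV data
    CL = CL if CL and CL > 0 else 0.1
    V1 = V1 if V1 and V1 > 0 else 2.0
    Q = Q if Q and Q > 0 else max(0.5 * CL, 0.05)
    V2 = V2 if V2 and V2 > 0 else 0.5 * V1

    F = 0.5
    if auc_iv and auc_po:
        F = min(max(auc_po / auc_iv, 0.05), 0.95)
    tmax = 4.0
    if po_curves:
        tmax = float(np.median([t[np.argmax(c)] for (t, c, _) in po_curves]))
        tmax = min(max(tmax, 0.5), 12.0)

    mu = {
        "ka": 1.0 / tmax, "Tk0": tmax, "Fr": 0.5, "V1": V1,
        "V2": V2, "Q": Q, "CL": CL, "F": F,
    }
    alternates: list = []
    b0 = 0.3
    if pooled_refine:
        try:
            mu, b0 = _pooled_nls(mu, iv_curves, po_curves, parameters, alternates)
        except Exception:
            alternates = []

    def build(m):
        return PopulationModel(
            mu={p: m[p] for p in parameters},
            beta_V1_WT0=0.0,
            b=b0,
            omega2={p: 0.1 for p in parameters},
            gamma2={p: 0.1 for p in parameters},
            parameters=parameters,
        )

    model = build(mu)
    model._alternates = [build(a) for a in alternates]  # for multi-start fits
    return model


def saem_fit_best(
    dataset: StudyDataset | Sequence[CompiledSubject],
    config: SAEMConfig,
    inits: Sequence[PopulationModel] | None = None,
    selection_samples: int = 300,
    **kw,
) -> FitResult:
    """SAEM from multiple starting models, keeping the best marginal likelihood.

    The absorption-shape surface of the mixed oral model is multimodal; the
    default starts are the pooled-fit initialization and (when distinct) the
    best pooled solution from the opposite side of the Fr axis.  Candidate
    fits are compared by importance-sampling marginal log-likelihood on a
    common random stream.
    """
    subjects = (
        compile_dataset(dataset) if isinstance(dataset, StudyDataset) else list(dataset)
    )
    if inits is None:
        base = initial_estimates(subjects)
        inits = [base] + list(getattr(base, "_alternates", []))
    best_fit, best_ll = None, -math.inf
    for j, init in enumerate(inits):
        cfg = SAEMConfig(**{**config.__dict__, "seed": config.seed + j})
        fit = saem_fit(subjects, cfg, init=init, compute_loglik=False, **kw)
        ll, _, _ = loglik_importance_sampling(
            subjects, fit, selection_samples,
            rng=np.random.default_rng(config.seed + 900001),
        )
        if ll > best_ll:
            best_fit, best_ll = fit, ll
    ll, se, ess = loglik_importance_sampling(
        subjects, best_fit, config.loglik_is_samples,
        rng=np.random.default_rng(config.seed + 104729),
    )
    best_fit.loglik = ll
    best_fit.loglik_se = se
    best_fit.is_ess = ess
    best_fit.bic = compute_bic(ll, best_fit.n_params, best_fit.n_subjects)
    return best_fit


def _pooled_nls(mu: dict, iv_curves, po_curves, parameters, alternates=None) -> dict:
    """Naive pooled least squares on log concentrations, per route.

    All observation points of all single-dose curves are stacked after
    dose-normalization, and the typical-value curve is fitted to the pooled
    cloud on the log scale (matching the proportional error).  The IV stage
    fixes the disposition; the oral stage then fits the absorption function.
    """
    from scipy.optimize import least_squares
    from .structural import iv_bolus_kernel, oral_mixed_kernel

    mu = dict(mu)
    if alternates is None:
        alternates = []
    two_cpt = "Q" in parameters
    if iv_curves:
        t = np.concatenate([c[0] for c in iv_curves])
        y = np.concatenate([np.log(np.maximum(c[1] / c[2], 1e-12)) for c in iv_curves])

        if two_cpt:
            def resid(x):
                CL, V1, Q, V2 = np.exp(x)
                pred = iv_bolus_kernel(CL, Q, V1, V2, 1.0, t)
                return np.log(np.maximum(pred, 1e-12)) - y

            # the implied C0 = dose/V1 must not dwarf the observed peak:
            # rules out spurious fast-distribution modes that hide before
            # the first sample
            v1_min = 1.0 / (3.0 * float(np.exp(y).max()))
            lo = np.log([1e-4, max(0.05, v1_min), 1e-4, 1e-3])
            hi = np.log([10.0, 100.0, 50.0, 100.0])
            best = None
            for x0 in (
                np.log([mu["CL"], mu["V1"], mu["Q"], mu["V2"]]),
                np.log([mu["CL"], mu["V1"], 2.0 * mu["CL"], 0.3 * mu["V1"]]),
            ):
                sol = least_squares(
                    resid, np.clip(x0, lo, hi), bounds=(lo, hi), max_nfev=400
                )
                if best is None or sol.cost < best.cost:
                    best = sol
            mu["CL"], mu["V1"], mu["Q"], mu["V2"] = np.exp(best.x)
        else:
            def resid(x):
                CL, V1 = np.exp(x)
                pred = iv_bolus_kernel(CL, 0.0, V1, 1.0, 1.0, t)
                return np.log(np.maximum(pred, 1e-12)) - y

            sol = least_squares(resid, np.log([mu["CL"], mu["V1"]]), max_nfev=400)
            mu["CL"], mu["V1"] = np.exp(sol.x)

    if po_curves:
        t = np.concatenate([c[0] for c in po_curves])
        y = np.concatenate([np.log(np.maximum(c[1] / c[2], 1e-12)) for c in po_curves])
        CL, V1 = mu["CL"], mu["V1"]
        Q = mu.get("Q", 0.0) if two_cpt else 0.0
        V2 = mu.get("V2", 1.0) if two_cpt else 1.0
        fit_f = bool(iv_curves)   # F only identifiable against IV data

        def resid(x):
            ka, Tk0 = np.exp(x[0]), np.exp(x[1])
            Fr = 1.0 / (1.0 + np.exp(-x[2]))
            F = 1.0 / (1.0 + np.exp(-x[3])) if fit_f else mu["F"]
            pred = oral_mixed_kernel(CL, Q, V1, V2, ka, Tk0, Fr, F, 1.0, t)
            return np.log(np.maximum(pred, 1e-12)) - y

        lo = np.array([math.log(1e-3), math.log(0.05), -6.0, -6.0])
        hi = np.array([math.log(50.0), math.log(48.0), 6.0, 6.0])
        f0 = math.log(mu["F"] / (1 - mu["F"]))
        sols = []
        # the absorption-shape surface is multimodal; symmetric multi-start
        for fr0 in (-1.5, 0.0, 1.5):
            for ka0 in (0.1, mu["ka"], 0.6):
                x0 = np.clip(
                    np.array([math.log(ka0), math.log(mu["Tk0"]), fr0, f0]), lo, hi
                )
                sol = least_squares(resid, x0, bounds=(lo, hi), max_nfev=300)
                sols.append(sol)
        sols.sort(key=lambda s: s.cost)
        best = sols[0]

        def absorption_of(sol):
            out = {
                "ka": float(np.exp(sol.x[0])),
                "Tk0": float(np.exp(sol.x[1])),
                "Fr": float(1.0 / (1.0 + np.exp(-sol.x[2]))),
            }
            if fit_f:
                out["F"] = float(1.0 / (1.0 + np.exp(-sol.x[3])))
            return out

        mu.update(absorption_of(best))
        # keep the best solution from the other side of the Fr axis as an
        # alternative absorption mode for multi-start population fits
        other = [s for s in sols[1:] if (
            (1.0 / (1.0 + np.exp(-s.x[2])) < 0.5) != (mu["Fr"] < 0.5)
        )]
        if other:
            alt = dict(mu)
            alt.update(absorption_of(other[0]))
            alternates.append(alt)
    for k, v in mu.items():
        if not np.isfinite(v) or v <= 0:
            raise ValueError("pooled fit produced an invalid value")
    for k in ("Fr", "F"):
        mu[k] = min(max(mu[k], 0.01), 0.99)
    # starting proportional-error constant from the pooled log residuals
    # (upper bound: pooled scatter also contains the between-curve variability)
    resids = []
    Q0, V20 = mu.get("Q", 0.0), mu.get("V2", 1.0)
    if iv_curves:
        t = np.concatenate([c[0] for c in iv_curves])
        y = np.concatenate([np.log(np.maximum(c[1] / c[2], 1e-12)) for c in iv_curves])
        pred = iv_bolus_kernel(mu["CL"], Q0, mu["V1"], V20, 1.0, t)
        resids.append(np.log(np.maximum(pred, 1e-12)) - y)
    if po_curves:
        t = np.concatenate([c[0] for c in po_curves])
        y = np.concatenate([np.log(np.maximum(c[1] / c[2], 1e-12)) for c in po_curves])
        pred = oral_mixed_kernel(
            mu["CL"], Q0, mu["V1"], V20,
            mu["ka"], mu["Tk0"], mu["Fr"], mu["F"], 1.0, t,
        )
        resids.append(np.log(np.maximum(pred, 1e-12)) - y)
    b0 = 0.3
    if resids:
        b0 = float(min(max(np.std(np.concatenate(resids)), 1e-3), 1.0))
    return mu, b0


def _auc(t, c) -> float:
    """Linear-trapezoid AUC extrapolated to infinity with the tail slope."""
    auc = float(np.trapezoid(c, t))
    if c.size >= 3 and c[-1] > 0:
        tail = np.polyfit(t[-3:], np.log(np.maximum(c[-3:], 1e-9)), 1)
        lz = -tail[0]
        if lz > 1e-4:
            auc += float(c[-1] / lz)
    return auc


def _strip_iv(iv_curves):
    """Biexponential curve stripping on the pooled geometric-mean IV profile."""
    times = iv_curves[0][0]
    mat = np.array([np.interp(times, t, c) for (t, c, _) in iv_curves])
    dose = float(np.mean([d for (_, _, d) in iv_curves]))
    c = np.exp(np.mean(np.log(np.maximum(mat, 1e-9)), axis=0))
    late = times >= max(times[-1] / 3.0, 8.0)
    if late.sum() < 3:
        late = times >= np.median(times)
    beta_fit = np.polyfit(times[late], np.log(c[late]), 1)
    lam_b, B = -beta_fit[0], math.exp(beta_fit[1])
    resid = c - B * np.exp(-lam_b * times)
    # alpha phase: early positive residuals only, before they sink into noise
    early = (resid > 0.05 * c.max()) & (times <= 0.5 * times[late][0])
    if early.sum() >= 2:
        alpha_fit = np.polyfit(times[early], np.log(resid[early]), 1)
        lam_a, A = -alpha_fit[0], math.exp(alpha_fit[1])
    else:
        lam_a, A = 10.0 * lam_b, 0.5 * B
    if lam_a <= lam_b:
        lam_a, A = 10.0 * lam_b, 0.5 * B
    V1 = dose / (A + B)
    k21 = (A * lam_b + B * lam_a) / (A + B)
    k10 = lam_a * lam_b / k21
    k12 = max(lam_a + lam_b - k21 - k10, 1e-4)
    return k10 * V1, V1, k12 * V1, k12 * V1 / k21
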