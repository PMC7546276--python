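"""The non-linear mixed-effects statistical layer.

Observation model: ``y_ij = F(phi_i, t_ij) + G(phi_i, t_ij) * eps_ij`` with
``eps_ij ~ N(0, 1)`` and a proportional residual scale ``G = b * F`` (floored
at a small constant so the likelihood stays finite at zero predictions).

Individual parameters arise from typical values ``mu`` perturbed by
inter-individual (eta, variance omega^2) and inter-occasion (kappa, variance
gamma^2) random effects on a transformed scale:

* log-normal parameters:    phi = mu * exp(eta + kappa)
* logit-normal parameters:  phi = inv_logit(logit(mu) + eta + kappa)

The absorption fractions ``Fr`` and ``F`` use the logit transform so
individual values stay in (0, 1); all other parameters are log-normal.
Bodyweight acts multiplicatively on the central volume::

    log V1_i = log V1_pop + beta * c(WT0_i) + eta_V1_i

where the default coding ``c`` is the log-normalized bodyweight
``log(WT0 / reference)`` (making beta a dimensionless allometric-style
exponent); raw-kg coding is available by configuration.

Observations below the quantification limit contribute the probability that
the true concentration lies in [0, LLOQ] (the M3 censored likelihood).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .dataio import StudyDataset
from .structural import (
    IV_BOLUS,
    ORAL,
    InvalidParameterError,
    iv_bolus_kernel,
    oral_mixed_kernel,
)

__all__ = [
    "PARAM_ORDER",
    "PopulationModel",
    "IndividualRealization",
    "Observation",
    "Covariates",
    "default_feline_model",
    "transform_parameter",
    "apply_covariate_V1",
    "residual_sd",
    "observation_loglik",
    "dataset_loglik",
    "compile_dataset",
    "CompiledSubject",
    "CompiledOccasion",
]

PARAM_ORDER = ("ka", "Tk0", "Fr", "V1", "V2", "Q", "CL", "F")
PARAM_ORDER_1CPT = ("ka", "Tk0", "Fr", "V1", "CL", "F")

DEFAULT_TRANSFORMS = {
    "ka": "log", "Tk0": "log", "Fr": "logit", "V1": "log",
    "V2": "log", "Q": "log", "CL": "log", "F": "logit",
}

RESIDUAL_FLOOR = 1e-6          # ng/ml, keeps G positive at zero prediction
LOG_PROB_FLOOR = math.log(1e-300)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def logit(x):
    x = np.asarray(x, dtype=float)
    return np.log(x) - np.log1p(-x)


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def norm_cdf(x):
    return 0.5 * erfc(-np.asarray(x, dtype=float) / math.sqrt(2.0))


def transform_parameter(mu: float, deviation: float, transform: str) -> float:
    """Individual parameter from typical value and total random deviation.

    ``deviation`` is eta + kappa on the transformed (Gaussian) scale.
    """
    if transform == "log":
        if mu <= 0:
            raise InvalidParameterError(f"log-normal mu must be > 0, got {mu}")
        return float(mu * np.exp(deviation))
    if transform == "logit":
        if not 0 < mu < 1:
            raise InvalidParameterError(f"logit-normal mu must be in (0,1), got {mu}")
        return float(inv_logit(logit(mu) + deviation))
    raise InvalidParameterError(f"unknown transform {transform!r}")


def apply_covariate_V1(
    V1pop: float,
    beta: float,
    WT0: float,
    reference_bodyweight: float,
    eta: float = 0.0,
    coding: str = "log_ratio",
) -> float:
    """Individual central volume with the bodyweight covariate effect.

    log V1_i = log V1pop + beta * c(WT0) + eta, where c is either the
    log-normalized bodyweight (default) or the raw bodyweight in kg.
    """
    if WT0 <= 0 or reference_bodyweight <= 0:
        raise ValueError("bodyweights must be positive")
    c = covariate_coding_value(WT0, reference_bodyweight, coding)
    return float(V1pop * np.exp(beta * c + eta))


def covariate_coding_value(WT0: float, reference: float, coding: str) -> float:
    if coding == "log_ratio":
        return math.log(WT0 / reference)
    if coding == "raw":
        return float(WT0)
    raise ValueError(f"unknown covariate coding {coding!r}")


def residual_sd(prediction, b: float, floor: float = RESIDUAL_FLOOR):
    """Proportional residual scale G = max(b * prediction, floor), ng/ml."""
    return np.maximum(b * np.asarray(prediction, dtype=float), floor)


@dataclass(frozen=True)
class Observation:
    """A single concentration record; BLQ rows carry the censoring bound."""

    time: float
    value: float
    blq: bool = False
    lloq: float = 0.5


@dataclass(frozen=True)
class Covariates:
    WT0: float
    sex: str = "n"
    fed: str = "fasted"

    def __post_init__(self) -> None:
        if self.WT0 <= 0:
            raise ValueError("WT0 must be positive")


@dataclass
class PopulationModel:
    """Fixed effects, random-effect variances and error model of the NLME."""

    mu: dict
    beta_V1_WT0: float = 0.0
    b: float = 0.30
    omega2: dict = field(default_factory=dict)   # IIV variances, transformed scale
    gamma2: dict = field(default_factory=dict)   # IOV variances, transformed scale
    transforms: dict = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    reference_bodyweight: float = 2.9
    covariate_coding: str = "log_ratio"
    error_model: str = "proportional"
    parameters: tuple = PARAM_ORDER

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise InvalidParameterError("proportional error constant b must be > 0")
        for p in self.parameters:
            if p not in self.mu:
                raise InvalidParameterError(f"missing typical value for {p}")
            tr = self.transforms.get(p, "log")
            if tr == "log" and self.mu[p] <= 0:
                raise InvalidParameterError(f"mu[{p}] must be > 0 for log transform")
            if tr == "logit" and not 0 < self.mu[p] < 1:
                raise InvalidParameterError(f"mu[{p}] must be in (0,1) for logit")
        self.omega2 = {p: float(self.omega2.get(p, 0.0)) for p in self.parameters}
        self.gamma2 = {p: float(self.gamma2.get(p, 0.0)) for p in self.parameters}
        if any(v < 0 for v in self.omega2.values()) or any(
            v < 0 for v in self.gamma2.values()
        ):
            raise InvalidParameterError("variances must be non-negative")

    # -- transformed-scale helpers -------------------------------------------------
    def m_vector(self) -> np.ndarray:
        """Typical values on the transformed (Gaussian) scale."""
        out = np.empty(len(self.parameters))
        for i, p in enumerate(self.parameters):
            out[i] = (
                math.log(self.mu[p])
                if self.transforms.get(p, "log") == "log"
                else float(logit(self.mu[p]))
            )
        return out

    def covariate_offsets(self, WT0: float) -> np.ndarray:
        """Additive transformed-scale offsets from covariates (V1 only)."""
        out = np.zeros(len(self.parameters))
        if self.beta_V1_WT0 != 0.0:
            c = covariate_coding_value(WT0, self.reference_bodyweight, self.covariate_coding)
            out[self.parameters.index("V1")] = self.beta_V1_WT0 * c
        return out

    def phi_from_psi(self, psi: np.ndarray) -> np.ndarray:
        """Natural-scale parameters from transformed values; broadcasts."""
        psi = np.asarray(psi, dtype=float)
        out = np.empty_like(psi)
        for i, p in enumerate(self.parameters):
            if self.transforms.get(p, "log") == "log":
                out[..., i] = np.exp(psi[..., i])
            else:
                out[..., i] = inv_logit(psi[..., i])
        return out

    def individual_params(
        self, covs: Covariates, eta: Mapping[str, float], kappa: Mapping[str, float]
    ) -> dict:
        """Natural-scale parameter dict for one subject-occasion."""
        m = self.m_vector() + self.covariate_offsets(covs.WT0)
        dev = np.array(
            [eta.get(p, 0.0) + kappa.get(p, 0.0) for p in self.parameters]
        )
        phi = self.phi_from_psi(m + dev)
        return dict(zip(self.parameters, phi.tolist()))

    def with_updates(self, **kw) -> "PopulationModel":
        return replace(self, **kw)


@dataclass
class IndividualRealization:
    """Random-effect draws for one subject: eta plus per-occasion kappa."""

    eta: dict
    kappa: dict  # occasion label -> dict of per-parameter deviations

    def deviations(self, occ) -> dict:
        k = self.kappa.get(occ, {})
        return {p: self.eta.get(p, 0.0) + k.get(p, 0.0) for p in self.eta}


def default_feline_model(
    omega: float = 0.1, gamma: float = 0.1, with_covariate: bool = True
) -> PopulationModel:
    """Reference model for vitacoxib in healthy cats.

    Typical values are the published point estimates for this drug and
    species; random-effect standard deviations default to 0.1 (roughly 10%
    CV) on every structural parameter, for both the inter-individual and
    inter-occasion levels.
    """
    return PopulationModel(
        mu={
            "ka": 0.13, "Tk0": 3.76, "Fr": 0.20, "V1": 2.88,
            "V2": 0.54, "Q": 0.52, "CL": 0.11, "F": 0.578,
        },
        beta_V1_WT0=0.41 if with_covariate else 0.0,
        b=0.30,
        omega2={p: omega ** 2 for p in PARAM_ORDER},
        gamma2={p: gamma ** 2 for p in PARAM_ORDER},
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def observation_loglik(obs: Observation, prediction: float, b: float) -> float:
    """Log-probability of one observation under the proportional-error model.

    Uncensored: Gaussian log-density with mean ``prediction`` and SD
    ``G = max(b*prediction, floor)``.  Censored (BLQ): log of the Gaussian
    probability mass on [0, LLOQ], floored at log(1e-300).
    """
    if prediction < 0:
        raise ValueError("prediction must be non-negative")
    g = float(residual_sd(prediction, b))
    if obs.blq:
        prob = float(norm_cdf((obs.lloq - prediction) / g) - norm_cdf((0.0 - prediction) / g))
        return max(math.log(max(prob, 0.0)) if prob > 0 else -math.inf, LOG_PROB_FLOOR)
    z = (obs.value - prediction) / g
    return -math.log(g) - 0.5 * z * z - _LOG_SQRT_2PI


def loglik_terms(dv, pred, blq, lloq, b, floor: float = RESIDUAL_FLOOR):
    """Vectorized per-observation log-likelihood; broadcasts over leading axes."""
    pred = np.asarray(pred, dtype=float)
    g = np.maximum(b * pred, floor)
    z = (dv - pred) / g
    ll = -np.log(g) - 0.5 * z * z - _LOG_SQRT_2PI
    blq = np.asarray(blq, dtype=bool)
    if blq.any():
        prob = norm_cdf((lloq - pred) / g) - norm_cdf(-pred / g)
        ll_cens = np.log(np.maximum(prob, 1e-300))
        ll = np.where(blq, np.maximum(ll_cens, LOG_PROB_FLOOR), ll)
    return ll


# ---------------------------------------------------------------------------
# compiled dataset structures (fast path shared by the estimator/diagnostics)
# ---------------------------------------------------------------------------

@dataclass
class CompiledOccasion:
    label: object
    times: np.ndarray
    dv: np.ndarray
    blq: np.ndarray
    lloq: np.ndarray
    ev_times: np.ndarray
    ev_amounts: np.ndarray
    ev_oral: np.ndarray  # bool per event
    active: np.ndarray | None = None  # parameter-relevance mask, filled later

    @property
    def has_oral(self) -> bool:
        return bool(self.ev_oral.any())

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass
class CompiledSubject:
    sid: int
    covs: Covariates
    occasions: list


def compile_dataset(dataset: StudyDataset) -> list:
    """Flatten a StudyDataset into per-subject/occasion numpy arrays."""
    subjects = []
    df = dataset.df
    for sid, sub in df.groupby("ID", sort=True):
        row0 = sub.iloc[0]
        covs = Covariates(
            WT0=float(row0["WT0"]), sex=str(row0["SEX"]), fed=str(row0["FED"])
        )
        occs = []
        for occ in dict.fromkeys(sub["OCC"].tolist()):
            grp = sub[sub["OCC"] == occ]
            doses = grp[grp["AMT"].astype(float) > 0]
            obs = grp[grp["MDV"].astype(float) == 0]
            occs.append(
                CompiledOccasion(
                    label=occ,
                    times=obs["TIME"].astype(float).to_numpy(),
                    dv=obs["DV"].astype(float).to_numpy(),
                    blq=obs["BLQ"].astype(float).to_numpy() > 0,
                    lloq=obs["LLOQ"].astype(float).to_numpy(),
                    ev_times=doses["TIME"].astype(float).to_numpy(),
                    ev_amounts=doses["AMT"].astype(float).to_numpy(),
                    ev_oral=(doses["ROUTE"].astype(str).str.lower() == ORAL).to_numpy(),
                )
            )
        subjects.append(CompiledSubject(sid=int(sid), covs=covs, occasions=occs))
    return subjects


def occasion_predictions(
    model: PopulationModel, occ: CompiledOccasion, phi_row: np.ndarray, times=None
) -> np.ndarray:
    """Concentration predictions for one occasion.

    ``phi_row`` holds natural-scale parameters in ``model.parameters`` order
    and may be a matrix ``(S, P)`` of parameter draws, in which case an
    ``(S, T)`` prediction matrix is returned.
    """
    phi = np.asarray(phi_row, dtype=float)
    squeeze = phi.ndim == 1
    phi = np.atleast_2d(phi)
    idx = {p: i for i, p in enumerate(model.parameters)}
    col = lambda p: phi[:, idx[p]][:, None]
    one_cpt = "Q" not in idx
    CL, V1 = col("CL"), col("V1")
    Q = 0.0 * CL if one_cpt else col("Q")
    V2 = np.ones_like(CL) if one_cpt else col("V2")
    t = occ.times if times is None else np.asarray(times, dtype=float)
    conc = np.zeros((phi.shape[0], t.size))
    for j in range(occ.ev_times.size):
        tau = t - occ.ev_times[j]
        mask = tau >= 0
        if not mask.any():
            continue
        tau_m = tau[mask]
        if occ.ev_oral[j]:
            contrib = oral_mixed_kernel(
                CL, Q, V1, V2,
                col("ka"), col("Tk0"), col("Fr"), col("F"),
                occ.ev_amounts[j], tau_m,
            )
        else:
            contrib = iv_bolus_kernel(CL, Q, V1, V2, occ.ev_amounts[j], tau_m)
        conc[:, mask] += contrib
    return conc[0] if squeeze else conc


def occasion_loglik(
    model: PopulationModel, occ: CompiledOccasion, phi_row: np.ndarray, b: float | None = None
):
    """Total observation log-likelihood for one occasion; broadcasts over draws."""
    pred = occasion_predictions(model, occ, phi_row)
    b = model.b if b is None else b
    ll = loglik_terms(occ.dv, pred, occ.blq, occ.lloq, b)
    return ll.sum(axis=-1)


def dataset_loglik(
    dataset: StudyDataset | Sequence[CompiledSubject],
    model: PopulationModel,
    realizations: Mapping[int, IndividualRealization],
) -> float:
    """Joint observation log-likelihood given individual random effects.

    Sums `observation_loglik` over every subject, occasion and observation;
    every subject present in the dataset must have a realization covering all
    of its occasions.
    """
    subjects = (
        compile_dataset(dataset) if isinstance(dataset, StudyDataset) else dataset
    )
    total = 0.0
    for sub in subjects:
        if sub.sid not in realizations:
            raise KeyError(f"missing realization for subject {sub.sid}")
        real = realizations[sub.sid]
        m = model.m_vector() + model.covariate_offsets(sub.covs.WT0)
        for occ in sub.occasions:
            if occ.label not in real.kappa and occ.n_obs:
                raise KeyError(
                    f"missing occasion {occ.label!r} realization for subject {sub.sid}"
                )
            dev = np.array(
                [
                    real.eta.get(p, 0.0) + real.kappa.get(occ.label, {}).get(p, 0.0)
                    for p in model.parameters
                ]
            )
            phi = model.phi_from_psi(m + dev)
            total += float(occasion_loglik(model, occ, phi))
    return total
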