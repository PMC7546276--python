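"""Synthetic six-study feline PK datasets.

The generator emulates the pooled experimental design behind the vitacoxib
cat analysis: 16 cats, two crossover groups, single I.V and P.O doses at
1/2/4 mg/kg, one 7-day q24h multiple-dose study, fixed rich sampling
schedules, bodyweights around 2.9 +/- 0.78 kg, log-/logit-normal IIV and IOV,
proportional residual error and left-censoring at the 0.5 ng/ml
quantification limit.  Each study is one occasion with its own clock;
washout between studies is assumed complete, so occasions are conditionally
independent given the subject-level effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import COLUMNS, StudyDataset
from .population import (
    CompiledSubject,
    PopulationModel,
    default_feline_model,
    occasion_predictions,
    residual_sd,
)
from .structural import IV_BOLUS, ORAL

__all__ = [
    "StudyDesign",
    "SyntheticDataset",
    "build_designs",
    "simulate_dataset",
    "batch_simulate_subject",
]

LLOQ_DEFAULT = 0.5  # ng/ml

_PO_TIMES = (0.33, 0.67, 1, 2, 4, 6, 8, 10, 12, 24, 36, 48)
_IV_TIMES = (0.08, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 10, 12, 24, 36, 48)
_GROUP_A = (9, 10, 11, 12, 13, 14, 15, 16)
_GROUP_B = (1, 2, 3, 4, 5, 6, 7, 8)


def _multidose_times(n_days: int) -> tuple:
    """Sampling clock for the 7-day study: rich day 1 and final day, trough
    and 5 h post-dose on intermediate days."""
    day1 = [0.33, 0.67, 1, 2, 4, 6, 8, 10, 12, 24]
    mid = []
    for d in range(2, n_days):
        mid += [24.0 * (d - 1), 24.0 * (d - 1) + 5.0]
    last = [24.0 * (n_days - 1) + t for t in (0.33, 0.67, 1, 2, 4, 6, 8, 10, 12, 24, 36, 48)]
    return tuple(sorted(set(day1 + mid + last)))


@dataclass(frozen=True)
class StudyDesign:
    """One study row: who was dosed, how, and when samples were drawn."""

    label: str
    subject_ids: tuple
    feeding: str          # "fasted" or "fed"
    route: str            # "iv" or "oral"
    dose_mg_kg: float
    sampling_times: tuple
    n_doses: int = 1
    dose_interval: float = 24.0

    @property
    def dose_times(self) -> tuple:
        return tuple(self.dose_interval * k for k in range(self.n_doses))


def build_designs(overrides: dict | None = None) -> list:
    """The default six-study design; overrides scale it down for fast tests.

    Recognized override keys: ``n_subjects`` (keep the first n cats of each
    study), ``studies`` (subset of labels to keep), ``n_doses_multi``
    (shorten the multiple-dose study).
    """
    overrides = dict(overrides or {})
    n_multi = int(overrides.pop("n_doses_multi", 7))
    designs = [
        StudyDesign("S1", _GROUP_A, "fasted", ORAL, 2.0, _PO_TIMES),
        StudyDesign("S2", _GROUP_A, "fasted", IV_BOLUS, 2.0, _IV_TIMES),
        StudyDesign("S3", _GROUP_A, "fed", ORAL, 2.0, _PO_TIMES),
        StudyDesign("S4", _GROUP_B, "fasted", ORAL, 1.0, _PO_TIMES),
        StudyDesign("S5", _GROUP_B, "fasted", ORAL, 4.0, _PO_TIMES),
        StudyDesign(
            "S6", _GROUP_A, "fasted", ORAL, 2.0,
            _multidose_times(n_multi), n_doses=n_multi,
        ),
    ]
    keep = overrides.pop("studies", None)
    if keep is not None:
        designs = [d for d in designs if d.label in keep]
        if not designs:
            raise ValueError(f"override 'studies'={keep} leaves no study")
    n_sub = overrides.pop("n_subjects", None)
    if n_sub is not None:
        n_sub = int(n_sub)
        if n_sub < 1:
            raise ValueError("n_subjects override must be >= 1")
        designs = [
            StudyDesign(
                d.label, d.subject_ids[: min(n_sub, len(d.subject_ids))],
                d.feeding, d.route, d.dose_mg_kg, d.sampling_times,
                d.n_doses, d.dose_interval,
            )
            for d in designs
        ]
    if overrides:
        raise ValueError(f"unknown design overrides: {sorted(overrides)}")
    return designs


@dataclass
class SyntheticDataset:
    """A simulated StudyDataset plus the generating truth for scoring."""

    dataset: StudyDataset
    truth: dict
    seed: int | None = None


def _lognormal_weights(rng, ids, mean: float, sd: float) -> dict:
    """Per-subject bodyweights, log-normal with the given arithmetic moments."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - 0.5 * sigma2
    draws = rng.normal(mu, math.sqrt(sigma2), size=len(ids))
    return {sid: float(np.exp(d)) for sid, d in zip(ids, draws)}


def simulate_dataset(
    designs,
    model: PopulationModel | None = None,
    bw_mean: float = 2.9,
    bw_sd: float = 0.78,
    seed: int | np.random.Generator | None = None,
    lloq: float = LLOQ_DEFAULT,
    bodyweights: dict | None = None,
) -> SyntheticDataset:
    """Simulate the full generative model over a set of study designs.

    Bodyweights are drawn once per cat and held fixed across its studies;
    eta is drawn per cat, kappa per cat-study; concentrations follow the
    structural model with the bodyweight effect on V1, perturbed by
    proportional noise; values below the LLOQ are flagged BLQ and replaced by
    the bound.
    """
    model = default_feline_model() if model is None else model
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    all_ids = sorted({sid for d in designs for sid in d.subject_ids})
    if bodyweights is None:
        bodyweights = _lognormal_weights(rng, all_ids, bw_mean, bw_sd)
    sexes = {sid: ("m" if rng.random() < 0.5 else "f") for sid in all_ids}

    P = len(model.parameters)
    omega = np.sqrt([model.omega2[p] for p in model.parameters])
    gamma = np.sqrt([model.gamma2[p] for p in model.parameters])
    etas = {sid: rng.normal(0.0, 1.0, P) * omega for sid in all_ids}
    kappas = {}

    rows = []
    for d in designs:
        for sid in d.subject_ids:
            wt = bodyweights[sid]
            kap = rng.normal(0.0, 1.0, P) * gamma
            kappas[(sid, d.label)] = kap
            m = model.m_vector() + model.covariate_offsets(wt)
            phi = model.phi_from_psi(m + etas[sid] + kap)
            amount = d.dose_mg_kg * wt * 1000.0
            occ = _occ_struct(d, amount)
            pred = occasion_predictions(model, occ, phi)
            eps = rng.normal(0.0, 1.0, pred.size)
            y = pred + residual_sd(pred, model.b) * eps
            base = dict(WT0=wt, SEX=sexes[sid], FED=d.feeding, LLOQ=lloq)
            for t in d.dose_times:
                rows.append(
                    dict(ID=sid, OCC=d.label, TIME=t, AMT=amount, ROUTE=d.route,
                         DV=np.nan, MDV=1, BLQ=0, **base)
                )
            for t, obs in zip(d.sampling_times, y):
                blq = obs < lloq
                rows.append(
                    dict(ID=sid, OCC=d.label, TIME=float(t),
                         AMT=0.0, ROUTE=".",
                         DV=lloq if blq else float(obs),
                         MDV=0, BLQ=int(blq), **base)
                )
    df = pd.DataFrame(rows)[COLUMNS]
    df = df.sort_values(["OCC", "ID", "TIME", "MDV"], ascending=[True, True, True, False])
    ds = StudyDataset(df.reset_index(drop=True))
    ds.validate()
    truth = {
        "mu": dict(model.mu),
        "beta_V1_WT0": model.beta_V1_WT0,
        "b": model.b,
        "omega2": dict(model.omega2),
        "gamma2": dict(model.gamma2),
        "bodyweights": bodyweights,
        "eta": {sid: dict(zip(model.parameters, e.tolist())) for sid, e in etas.items()},
        "kappa": {
            f"{sid}:{lbl}": dict(zip(model.parameters, k.tolist()))
            for (sid, lbl), k in kappas.items()
        },
    }
    return SyntheticDataset(dataset=ds, truth=truth, seed=seed_val)


def _occ_struct(design: StudyDesign, amount: float):
    """A CompiledOccasion-shaped record straight from a design row."""
    from .population import CompiledOccasion

    times = np.asarray(design.sampling_times, dtype=float)
    ev_times = np.asarray(design.dose_times, dtype=float)
    return CompiledOccasion(
        label=design.label,
        times=times,
        dv=np.zeros_like(times),
        blq=np.zeros(times.size, dtype=bool),
        lloq=np.full(times.size, LLOQ_DEFAULT),
        ev_times=ev_times,
        ev_amounts=np.full(ev_times.size, amount),
        ev_oral=np.full(ev_times.size, design.route == ORAL),
    )


def batch_simulate_subject(
    model: PopulationModel,
    subject: CompiledSubject,
    n_replicates: int,
    rng: np.random.Generator,
    include_noise: bool = True,
):
    """Simulate a subject's full observation vector ``n_replicates`` times.

    Eta draws are shared across the subject's occasions within a replicate
    (kappa is redrawn per occasion), reproducing the between/within-occasion
    correlation structure.  Returns a list of ``(K, T_occ)`` arrays, one per
    occasion, in occasion order.
    """
    P = len(model.parameters)
    omega = np.sqrt([model.omega2[p] for p in model.parameters])
    gamma = np.sqrt([model.gamma2[p] for p in model.parameters])
    m = model.m_vector() + model.covariate_offsets(subject.covs.WT0)
    eta = rng.normal(0.0, 1.0, (n_replicates, P)) * omega
    out = []
    for occ in subject.occasions:
        kap = rng.normal(0.0, 1.0, (n_replicates, P)) * gamma
        phi = model.phi_from_psi(m + eta + kap)
        pred = occasion_predictions(model, occ, phi)
        if include_noise:
            eps = rng.normal(0.0, 1.0, pred.shape)
            pred = pred + residual_sd(pred, model.b) * eps
        out.append(pred)
    return out
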