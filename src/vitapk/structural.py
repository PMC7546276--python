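"""Two-compartment disposition model with I.V bolus and mixed oral absorption.

The disposition system is the classical mammillary two-compartment model
parameterized by systemic clearance ``CL``, intercompartmental clearance ``Q``
and the central/peripheral volumes ``V1``/``V2``.  Oral input is the sum of a
first-order process (fraction ``Fr`` of the absorbed dose, rate constant
``ka``) and a zero-order process (fraction ``1 - Fr``, delivered at constant
rate over a duration ``Tk0``), both starting at the dose time with no lag.
``F`` is the oral bioavailability; intravenous doses bypass absorption and
``F`` entirely.

Unit convention (package-wide): amounts in µg, volumes in L, time in h, so
concentrations are µg/L which is numerically identical to ng/ml.  Doses given
per kg of bodyweight are converted with ``mg_per_kg * bodyweight_kg * 1000``.

All concentration functions are closed-form superpositions of exponentials and
broadcast over numpy arrays: parameters shaped ``(S, 1)`` against times shaped
``(T,)`` give an ``(S, T)`` concentration matrix, which is what the SAEM
machinery and the simulation diagnostics rely on for speed.  An independent
adaptive ODE integrator (`ode_profile`) is kept as a numerical oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DispositionParams",
    "AbsorptionParams",
    "DoseEvent",
    "ConcentrationProfile",
    "MicroConstants",
    "DerivedMetrics",
    "derive_micro_constants",
    "conc_iv_bolus",
    "conc_oral_mixed",
    "simulate_profile",
    "derived_metrics",
    "ode_profile",
    "ode_mass_balance",
]

IV_BOLUS = "iv"
ORAL = "oral"


class InvalidParameterError(ValueError):
    """A structural or absorption parameter violates its domain."""


@dataclass(frozen=True)
class DispositionParams:
    """Two-compartment disposition parameters.

    CL : systemic clearance, L/h
    Q  : intercompartmental clearance, L/h (0 collapses to one compartment)
    V1 : central volume of distribution, L
    V2 : peripheral volume of distribution, L
    """

    CL: float
    Q: float
    V1: float
    V2: float

    def __post_init__(self) -> None:
        if not (self.CL > 0 and self.V1 > 0 and self.V2 > 0):
            raise InvalidParameterError(
                f"CL, V1, V2 must be strictly positive, got CL={self.CL}, "
                f"V1={self.V1}, V2={self.V2}"
            )
        if self.Q < 0:
            raise InvalidParameterError(f"Q must be non-negative, got Q={self.Q}")


@dataclass(frozen=True)
class AbsorptionParams:
    """Mixed zero-/first-order oral absorption parameters.

    ka  : first-order absorption rate constant, 1/h
    Tk0 : duration of the zero-order absorption phase, h
    Fr  : fraction of the absorbed dose entering by the first-order path
    F   : oral bioavailability
    """

    ka: float
    Tk0: float
    Fr: float
    F: float

    def __post_init__(self) -> None:
        if not self.ka > 0:
            raise InvalidParameterError(f"ka must be positive, got {self.ka}")
        if not self.Tk0 > 0:
            raise InvalidParameterError(f"Tk0 must be positive, got {self.Tk0}")
        if not 0 < self.Fr <= 1:
            raise InvalidParameterError(f"Fr must lie in (0, 1], got {self.Fr}")
        if not 0 < self.F <= 1:
            raise InvalidParameterError(f"F must lie in (0, 1], got {self.F}")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: time (h), amount (µg) and route."""

    time: float
    amount: float
    route: str

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise InvalidParameterError(f"dose amount must be >= 0, got {self.amount}")
        if self.time < 0:
            raise InvalidParameterError(f"dose time must be >= 0, got {self.time}")
        if self.route not in (IV_BOLUS, ORAL):
            raise InvalidParameterError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Paired times (h) and central-compartment concentrations (ng/ml)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


class MicroConstants(NamedTuple):
    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float


def derive_micro_constants(p: DispositionParams) -> MicroConstants:
    """Micro rate constants and hybrid exponents of the mammillary system.

    k10 = CL/V1, k12 = Q/V1, k21 = Q/V2; alpha and beta are the roots of
    s^2 - (k10+k12+k21) s + k10*k21, with alpha >= beta >= 0.  In the
    degenerate limit Q = 0 the peripheral compartment decouples, beta = 0 and
    the terminal slope equals k10.
    """
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    s = k10 + k12 + k21
    prod = k10 * k21
    disc = math.sqrt(max(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + disc)
    beta = prod / alpha if alpha > 0 else 0.0
    return MicroConstants(k10, k12, k21, alpha, beta)


# ---------------------------------------------------------------------------
# vectorized closed-form kernels
# ---------------------------------------------------------------------------

def disposition_terms(CL, Q, V1, V2):
    """Exponents and central-compartment coefficients, broadcasting over arrays.

    Returns ``(lam1, lam2, c1, c2)`` such that the unit-impulse (I.V bolus of
    1 µg) central concentration is ``c1*exp(-lam1*t) + c2*exp(-lam2*t)``.
    A repeated root (alpha == beta) is measure-zero; k21 is nudged by one part
    in 1e9 to keep the two-exponential form well-defined.
    """
    CL, Q, V1, V2 = (np.asarray(x, dtype=float) for x in (CL, Q, V1, V2))
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    prod = k10 * k21
    disc2 = s * s - 4.0 * prod
    # nudge near-repeated roots off the diagonal
    tiny = disc2 < (1e-18 * s * s)
    if np.any(tiny):
        k21 = np.where(tiny, k21 * (1.0 + 1e-9) + 1e-15, k21)
        s = k10 + k12 + k21
        prod = k10 * k21
        disc2 = s * s - 4.0 * prod
    disc = np.sqrt(np.maximum(disc2, 0.0))
    alpha = 0.5 * (s + disc)
    beta = np.where(alpha > 0, prod / np.maximum(alpha, 1e-300), 0.0)
    denom = np.where(disc > 0, disc, 1.0)
    A = (alpha - k21) / denom
    B = (k21 - beta) / denom
    return alpha, beta, A / V1, B / V1


def _exp_integral(lam, t):
    """(1 - exp(-lam*t))/lam with a stable lam -> 0 limit, elementwise."""
    lam, t = np.broadcast_arrays(np.asarray(lam, float), np.asarray(t, float))
    out = np.empty_like(lam)
    small = np.abs(lam * t) < 1e-12
    lam_safe = np.where(small, 1.0, lam)
    out = -np.expm1(-lam_safe * t) / lam_safe
    return np.where(small, t, out)


def _conv_first_order(lam, ka, t):
    """Convolution kernel (exp(-lam t) - exp(-ka t)) / (ka - lam), stable at ka ~ lam."""
    lam, ka, t = np.broadcast_arrays(
        np.asarray(lam, float), np.asarray(ka, float), np.asarray(t, float)
    )
    d = ka - lam
    near = np.abs(d * t) < 1e-7
    d_safe = np.where(near, 1.0, d)
    direct = (np.exp(-lam * t) - np.exp(-ka * t)) / d_safe
    series = t * np.exp(-ka * t) * (1.0 + 0.5 * d * t)
    return np.where(near, series, direct)


def iv_bolus_kernel(CL, Q, V1, V2, dose, tau):
    """Central concentration after an I.V bolus, tau = time since dose (>= 0)."""
    lam1, lam2, c1, c2 = disposition_terms(CL, Q, V1, V2)
    tau = np.asarray(tau, dtype=float)
    conc = dose * (c1 * np.exp(-lam1 * tau) + c2 * np.exp(-lam2 * tau))
    return conc


def oral_mixed_kernel(CL, Q, V1, V2, ka, Tk0, Fr, F, dose, tau):
    """Central concentration after an oral dose with mixed absorption.

    First-order path: amount Fr*F*dose input at rate ka.  Zero-order path:
    amount (1-Fr)*F*dose at constant rate over [0, Tk0].  Both convolved with
    the two-compartment impulse response; both start at the dose time.
    """
    lam1, lam2, c1, c2 = disposition_terms(CL, Q, V1, V2)
    tau = np.asarray(tau, dtype=float)
    amt_fo = Fr * F * dose
    amt_zo = (1.0 - Fr) * F * dose

    conc = amt_fo * ka * (
        c1 * _conv_first_order(lam1, ka, tau) + c2 * _conv_first_order(lam2, ka, tau)
    )
    # zero-order: rate amt_zo/Tk0 over [0, Tk0]
    tau_off = np.maximum(tau - Tk0, 0.0)
    rate = amt_zo / Tk0
    conc = conc + rate * (
        c1 * (_exp_integral(lam1, tau) - _exp_integral(lam1, tau_off))
        + c2 * (_exp_integral(lam2, tau) - _exp_integral(lam2, tau_off))
    )
    return conc


# ---------------------------------------------------------------------------
# public scalar-parameter API
# ---------------------------------------------------------------------------

def conc_iv_bolus(p: DispositionParams, dose: float, t) -> np.ndarray | float:
    """Concentration (ng/ml) after an I.V bolus at t = 0.

    The t = 0 value is the right limit dose/V1.  Negative times are a domain
    error (use `simulate_profile` for pre-dose zeros).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = iv_bolus_kernel(p.CL, p.Q, p.V1, p.V2, dose, t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def conc_oral_mixed(
    p: DispositionParams, a: AbsorptionParams, dose: float, t
) -> np.ndarray | float:
    """Concentration (ng/ml) after an oral dose at t = 0 with mixed absorption."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = oral_mixed_kernel(
        p.CL, p.Q, p.V1, p.V2, a.ka, a.Tk0, a.Fr, a.F, dose, t_arr
    )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _check_sorted(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        raise ValueError(f"{name} must be sorted in non-decreasing time order")
    return arr


def simulate_profile(
    events: Sequence[DoseEvent],
    p: DispositionParams,
    a: AbsorptionParams | None,
    times,
) -> ConcentrationProfile:
    """Multi-dose concentration profile by linear superposition.

    The model is linear and time-invariant, so the response to an arbitrary
    mixed I.V/P.O dosing history is the sum of shifted single-dose solutions.
    Times before the first event evaluate to zero.
    """
    _check_sorted([e.time for e in events], "dose events")
    t = _check_sorted(times, "times")
    conc = np.zeros_like(t)
    for ev in events:
        if ev.amount == 0:
            continue
        tau = t - ev.time
        mask = tau >= 0
        if not np.any(mask):
            continue
        if ev.route == IV_BOLUS:
            conc[mask] += iv_bolus_kernel(p.CL, p.Q, p.V1, p.V2, ev.amount, tau[mask])
        else:
            if a is None:
                raise InvalidParameterError("oral dose event requires AbsorptionParams")
            conc[mask] += oral_mixed_kernel(
                p.CL, p.Q, p.V1, p.V2, a.ka, a.Tk0, a.Fr, a.F, ev.amount, tau[mask]
            )
    return ConcentrationProfile(t, conc)


class DerivedMetrics(NamedTuple):
    VSS: float          # steady-state volume of distribution, L
    t_half_eff: float   # effective half-life 0.693*VSS/CL, h
    CL_ml_min: float    # clearance in ml/min
    VSS_per_kg: float   # VSS scaled by the reference bodyweight, L/kg


def derived_metrics(p: DispositionParams, reference_bodyweight: float) -> DerivedMetrics:
    """Secondary disposition metrics: VSS, effective half-life, unit conversions."""
    if reference_bodyweight <= 0:
        raise ValueError("reference bodyweight must be positive")
    vss = p.V1 + p.V2
    return DerivedMetrics(
        VSS=vss,
        t_half_eff=math.log(2.0) * vss / p.CL,
        CL_ml_min=p.CL * 1000.0 / 60.0,
        VSS_per_kg=vss / reference_bodyweight,
    )


# ---------------------------------------------------------------------------
# independent ODE oracle
# ---------------------------------------------------------------------------

def _zero_order_rate(t: float, windows) -> float:
    rate = 0.0
    for (t0, t1, r) in windows:
        if t0 <= t < t1:
            rate += r
    return rate


def ode_profile(
    events: Sequence[DoseEvent],
    p: DispositionParams,
    a: AbsorptionParams | None,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    full_state: bool = False,
):
    """Adaptive-step ODE solution of the same dosing history.

    State is (gut amount, central amount, peripheral amount, eliminated
    amount); oral zero-order input enters as a piecewise-constant forcing
    term and the integration is split at every dose time and zero-order
    switch-off so the right-hand side is smooth on each segment.  Used as a
    numerical oracle for the closed-form solutions.
    """
    t_eval = np.asarray(times, dtype=float)
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    ka = a.ka if a is not None else 0.0

    windows = []
    bolus = []  # (time, d_gut, d_central)
    for ev in events:
        if ev.route == IV_BOLUS:
            bolus.append((ev.time, 0.0, ev.amount))
        else:
            if a is None:
                raise InvalidParameterError("oral dose event requires AbsorptionParams")
            bolus.append((ev.time, a.Fr * a.F * ev.amount, 0.0))
            amt_zo = (1.0 - a.Fr) * a.F * ev.amount
            windows.append((ev.time, ev.time + a.Tk0, amt_zo / a.Tk0))

    horizon = float(t_eval[-1]) if t_eval.size else 0.0
    breaks = sorted(
        {0.0, horizon}
        | {t for (t, _, _) in bolus if t <= horizon}
        | {t1 for (_, t1, _) in windows if t1 < horizon}
        | {t0 for (t0, _, _) in windows if t0 <= horizon}
    )

    def rhs(t, y):
        g, c, per, _ = y
        r0 = _zero_order_rate(t, windows)
        return [
            -ka * g,
            ka * g + r0 - (k10 + k12) * c + k21 * per,
            k12 * c - k21 * per,
            k10 * c,
        ]

    y = np.zeros(4)
    out = np.zeros((4, t_eval.size))
    done = np.zeros(t_eval.size, dtype=bool)

    for left, right in zip(breaks[:-1], breaks[1:]):
        for (tb, dg, dc) in bolus:
            if abs(tb - left) < 1e-12:
                y[0] += dg
                y[1] += dc
        seg_mask = (~done) & (t_eval >= left) & (t_eval <= right)
        seg_times = t_eval[seg_mask]
        if right > left:
            eval_at = np.unique(np.append(seg_times, right))
            sol = solve_ivp(
                rhs,
                (left, right),
                y,
                method="LSODA",
                t_eval=eval_at,
                rtol=rtol,
                atol=atol,
            )
            if seg_times.size:
                idx = np.searchsorted(eval_at, seg_times)
                out[:, seg_mask] = sol.y[:, idx]
                done |= seg_mask
            y = sol.y[:, -1]
        elif seg_times.size:
            out[:, seg_mask] = y[:, None]
            done |= seg_mask
    # exact-time samples at t=0 before any integration
    zero_mask = (~done) & (t_eval <= breaks[0])
    if np.any(zero_mask):
        out[:, zero_mask] = 0.0

    conc = out[1] / p.V1
    if full_state:
        return ConcentrationProfile(t_eval, conc), out, windows
    return ConcentrationProfile(t_eval, conc)


def ode_mass_balance(
    events: Sequence[DoseEvent],
    p: DispositionParams,
    a: AbsorptionParams,
    times,
) -> np.ndarray:
    """Total drug accounted for at each time, as a fraction of sum(F*dose).

    Counts gut + central + peripheral + eliminated amounts plus the portion of
    each zero-order input not yet delivered; for a mass-conserving model this
    is identically 1 after the first dose.
    """
    _, state, windows = ode_profile(events, p, a, times, full_state=True)
    t = np.asarray(times, dtype=float)
    undelivered = np.zeros_like(t)
    for (t0, t1, r) in windows:
        undelivered += r * np.clip(t1 - np.maximum(t, t0), 0.0, t1 - t0)
    total_dose = sum(
        (a.F if ev.route == ORAL else 1.0) * ev.amount for ev in events
    )
    dosed = np.zeros_like(t)
    for ev in events:
        frac = a.F if ev.route == ORAL else 1.0
        dosed += np.where(t >= ev.time, frac * ev.amount, 0.0)
    accounted = state.sum(axis=0) + undelivered
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(dosed > 0, accounted / dosed, 1.0)
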