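"""Hot-loop structural/likelihood kernels for the SAEM sampler.

Scalar-parameter re-implementations of the closed-form two-compartment
solutions in `structural` plus the proportional-error/M3 likelihood, written
as tight loops so they can be compiled with numba when it is installed.  The
pure-Python definitions are kept as a fallback and the two paths are
cross-checked against the vectorized reference implementation in the test
suite.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["occ_conc", "occ_loglik", "HAVE_NUMBA"]

_RESIDUAL_FLOOR = 1e-6
_LOG_PROB_FLOOR = math.log(1e-300)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)


def _occ_conc_impl(
    ka, Tk0, Fr, V1, V2, Q, CL, F,
    times, ev_times, ev_amounts, ev_oral,
):
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    prod = k10 * k21
    disc2 = s * s - 4.0 * prod
    if disc2 < 1e-18 * s * s:
        k21 = k21 * (1.0 + 1e-9) + 1e-15
        s = k10 + k12 + k21
        prod = k10 * k21
        disc2 = s * s - 4.0 * prod
    disc = math.sqrt(disc2) if disc2 > 0.0 else 0.0
    alpha = 0.5 * (s + disc)
    beta = prod / alpha if alpha > 0.0 else 0.0
    d = disc if disc > 0.0 else 1.0
    c1 = (alpha - k21) / d / V1
    c2 = (k21 - beta) / d / V1

    T = times.shape[0]
    conc = np.zeros(T)
    for j in range(ev_times.shape[0]):
        t0 = ev_times[j]
        amt = ev_amounts[j]
        if amt == 0.0:
            continue
        if ev_oral[j]:
            amt_fo = Fr * F * amt * ka
            rate = (1.0 - Fr) * F * amt / Tk0
            da = ka - alpha
            db = ka - beta
            for i in range(T):
                tau = times[i] - t0
                if tau < 0.0:
                    continue
                ea = math.exp(-alpha * tau)
                eb = math.exp(-beta * tau)
                ek = math.exp(-ka * tau)
                if abs(da) > 1e-8 * ka:
                    fa = (ea - ek) / da
                else:
                    fa = tau * ek
                if abs(db) > 1e-8 * ka:
                    fb = (eb - ek) / db
                else:
                    fb = tau * ek
                val = amt_fo * (c1 * fa + c2 * fb)
                tau2 = tau - Tk0
                if tau2 < 0.0:
                    tau2 = 0.0
                za = (math.exp(-alpha * tau2) - ea) / alpha
                if beta > 1e-12:
                    zb = (math.exp(-beta * tau2) - eb) / beta
                else:
                    zb = tau - tau2
                val += rate * (c1 * za + c2 * zb)
                conc[i] += val
        else:
            for i in range(T):
                tau = times[i] - t0
                if tau < 0.0:
                    continue
                conc[i] += amt * (
                    c1 * math.exp(-alpha * tau) + c2 * math.exp(-beta * tau)
                )
    return conc


def _make_loglik(conc_fn):
    def _occ_loglik_impl(
        ka, Tk0, Fr, V1, V2, Q, CL, F,
        times, ev_times, ev_amounts, ev_oral,
        dv, blq, lloq, b,
    ):
        conc = conc_fn(
            ka, Tk0, Fr, V1, V2, Q, CL, F, times, ev_times, ev_amounts, ev_oral
        )
        total = 0.0
        for i in range(times.shape[0]):
            g = b * conc[i]
            if g < _RESIDUAL_FLOOR:
                g = _RESIDUAL_FLOOR
            if blq[i]:
                zu = (lloq[i] - conc[i]) / g
                zl = -conc[i] / g
                prob = 0.5 * (math.erfc(-zu / _SQRT2) - math.erfc(-zl / _SQRT2))
                if prob < 1e-300:
                    prob = 1e-300
                ll = math.log(prob)
                if ll < _LOG_PROB_FLOOR:
                    ll = _LOG_PROB_FLOOR
                total += ll
            else:
                z = (dv[i] - conc[i]) / g
                total += -math.log(g) - 0.5 * z * z - _LOG_SQRT_2PI
        return total

    return _occ_loglik_impl


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    occ_conc = njit(cache=True, nogil=True)(_occ_conc_impl)
    occ_loglik = njit(cache=True, nogil=True)(_make_loglik(occ_conc))
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    occ_conc = _occ_conc_impl
    occ_loglik = _make_loglik(_occ_conc_impl)
    HAVE_NUMBA = False
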