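"""Two-compartment closed forms against identities and the ODE oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitapk import (
    AbsorptionParams,
    ConcentrationProfile,
    DispositionParams,
    DoseEvent,
    conc_iv_bolus,
    conc_oral_mixed,
    derive_micro_constants,
    derived_metrics,
    ode_profile,
    simulate_profile,
)
from vitapk.structural import InvalidParameterError, ode_mass_balance

DOSE = 5800.0  # µg, 2 mg/kg at the 2.9 kg study-mean bodyweight


valid_disposition = st.builds(
    DispositionParams,
    CL=st.floats(0.01, 2.0),
    Q=st.floats(0.01, 5.0),
    V1=st.floats(0.5, 20.0),
    V2=st.floats(0.05, 20.0),
)


class TestMicroConstants:
    def test_published_point_estimates(self, disposition):
        mc = derive_micro_constants(disposition)
        assert mc.k10 == pytest.approx(0.03819, abs=5e-6)
        assert mc.k12 == pytest.approx(0.18056, abs=5e-6)
        assert mc.k21 == pytest.approx(0.96296, abs=5e-6)
        assert mc.alpha > mc.beta > 0

    def test_decoupled_limit_without_intercompartmental_flow(self):
        p = DispositionParams(CL=0.11, Q=0.0, V1=2.88, V2=0.54)
        mc = derive_micro_constants(p)
        assert mc.beta == 0.0
        assert mc.alpha == pytest.approx(mc.k10)

    @given(valid_disposition)
    @settings(max_examples=100, deadline=None)
    def test_characteristic_polynomial_identities(self, p):
        mc = derive_micro_constants(p)
        s = mc.k10 + mc.k12 + mc.k21
        assert mc.alpha + mc.beta == pytest.approx(s, rel=1e-12)
        assert mc.alpha * mc.beta == pytest.approx(mc.k10 * mc.k21, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            DispositionParams(CL=-0.1, Q=0.5, V1=2.9, V2=0.5)
        with pytest.raises(InvalidParameterError):
            DispositionParams(CL=0.1, Q=0.5, V1=0.0, V2=0.5)


class TestSingleDose:
    def test_zero_dose_gives_zero(self, disposition):
        assert conc_iv_bolus(disposition, 0.0, 5.0) == 0.0

    def test_iv_initial_concentration_is_dose_over_v1(self, disposition):
        assert conc_iv_bolus(disposition, DOSE, 0.0) == pytest.approx(
            DOSE / disposition.V1
        )
        assert DOSE / disposition.V1 == pytest.approx(2013.9, abs=0.1)

    def test_negative_time_rejected(self, disposition, absorption):
        with pytest.raises(ValueError):
            conc_iv_bolus(disposition, DOSE, -1.0)
        with pytest.raises(ValueError):
            conc_oral_mixed(disposition, absorption, DOSE, -0.5)

    def test_iv_matches_ode_oracle(self, disposition, absorption):
        t = np.array([0.25, 1.0, 8.0, 24.0, 48.0])
        cf = conc_iv_bolus(disposition, DOSE, t)
        od = ode_profile([DoseEvent(0.0, DOSE, "iv")], disposition, absorption, t)
        assert np.max(np.abs(cf - od.concentrations) / cf) < 1e-8

    def test_oral_matches_ode_oracle(self, disposition, absorption):
        t = np.array([1.0, 3.76, 6.0, 12.0, 24.0])
        cf = conc_oral_mixed(disposition, absorption, DOSE, t)
        od = ode_profile([DoseEvent(0.0, DOSE, "oral")], disposition, absorption, t)
        assert np.max(np.abs(cf - od.concentrations) / cf) < 1e-6

    def test_oral_starts_at_zero(self, disposition, absorption):
        assert conc_oral_mixed(disposition, absorption, DOSE, 0.0) == 0.0

    def test_pure_first_order_reduction(self, disposition):
        a = AbsorptionParams(ka=0.3, Tk0=2.0, Fr=1.0, F=0.578)
        t = np.array([0.5, 2.0, 8.0, 24.0])
        cf = conc_oral_mixed(disposition, a, DOSE, t)
        od = ode_profile([DoseEvent(0.0, DOSE, "oral")], disposition, a, t)
        assert np.max(np.abs(cf - od.concentrations) / cf) < 1e-6

    def test_continuity_at_zero_order_cutoff(self, disposition, absorption):
        eps = 1e-7
        left = conc_oral_mixed(disposition, absorption, DOSE, absorption.Tk0 - eps)
        right = conc_oral_mixed(disposition, absorption, DOSE, absorption.Tk0 + eps)
        assert left == pytest.approx(right, rel=1e-5)

    def test_iv_profile_monotone_decreasing(self, disposition):
        t = np.linspace(0.0, 72.0, 500)
        c = conc_iv_bolus(disposition, DOSE, t)
        assert np.all(np.diff(c) < 0)

    @given(valid_disposition, st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_dose_linearity(self, p, t):
        a = AbsorptionParams(ka=0.13, Tk0=3.76, Fr=0.2, F=0.578)
        assert conc_iv_bolus(p, 2 * DOSE, t) == pytest.approx(
            2 * conc_iv_bolus(p, DOSE, t), rel=1e-12
        )
        assert conc_oral_mixed(p, a, 2 * DOSE, t) == pytest.approx(
            2 * conc_oral_mixed(p, a, DOSE, t), rel=1e-12
        )


class TestSuperposition:
    def test_single_event_equals_single_dose(self, disposition, absorption):
        t = np.array([0.5, 4.0, 30.0])
        prof = simulate_profile(
            [DoseEvent(0.0, DOSE, "oral")], disposition, absorption, t
        )
        direct = conc_oral_mixed(disposition, absorption, DOSE, t)
        np.testing.assert_allclose(prof.concentrations, direct, rtol=1e-12)

    def test_two_half_doses_equal_one(self, disposition, absorption):
        t = np.linspace(0.0, 48.0, 50)
        one = simulate_profile(
            [DoseEvent(0.0, DOSE, "oral")], disposition, absorption, t
        )
        two = simulate_profile(
            [DoseEvent(0.0, DOSE / 2, "oral"), DoseEvent(0.0, DOSE / 2, "oral")],
            disposition, absorption, t,
        )
        np.testing.assert_allclose(one.concentrations, two.concentrations, rtol=1e-12)

    def test_pre_dose_concentrations_are_zero(self, disposition, absorption):
        prof = simulate_profile(
            [DoseEvent(10.0, DOSE, "iv")], disposition, absorption,
            np.array([0.0, 5.0, 9.99, 10.0]),
        )
        assert np.all(prof.concentrations[:3] == 0.0)
        assert prof.concentrations[3] > 0.0

    def test_seven_daily_doses_match_ode_trough(self, disposition, absorption):
        events = [DoseEvent(24.0 * k, DOSE, "oral") for k in range(7)]
        t = np.array([144.0, 168.0])
        cf = simulate_profile(events, disposition, absorption, t)
        od = ode_profile(events, disposition, absorption, t)
        assert np.max(
            np.abs(cf.concentrations - od.concentrations) / cf.concentrations
        ) < 1e-6

    def test_unsorted_inputs_rejected(self, disposition, absorption):
        with pytest.raises(ValueError):
            simulate_profile(
                [DoseEvent(24.0, DOSE, "oral"), DoseEvent(0.0, DOSE, "oral")],
                disposition, absorption, [0.0, 1.0],
            )
        with pytest.raises(ValueError):
            simulate_profile(
                [DoseEvent(0.0, DOSE, "oral")], disposition, absorption, [2.0, 1.0]
            )

    def test_oral_mass_balance(self, disposition, absorption):
        frac = ode_mass_balance(
            [DoseEvent(0.0, DOSE, "oral")], disposition, absorption,
            np.array([0.5, 2.0, 3.76, 10.0, 48.0]),
        )
        np.testing.assert_allclose(frac, 1.0, rtol=1e-8)


class TestDerivedMetrics:
    def test_steady_state_volume(self, disposition):
        m = derived_metrics(disposition, 2.9)
        assert m.VSS == pytest.approx(3.42, abs=1e-12)

    def test_clearance_unit_conversion(self, disposition):
        m = derived_metrics(disposition, 2.9)
        assert round(m.CL_ml_min, 1) == 1.8

    def test_volume_per_kg(self, disposition):
        m = derived_metrics(disposition, 2.9)
        assert m.VSS_per_kg == pytest.approx(1.18, abs=0.01)

    def test_effective_half_life(self, disposition):
        m = derived_metrics(disposition, 2.9)
        assert m.t_half_eff == pytest.approx(21.5, rel=0.01)

    def test_invalid_reference_weight(self, disposition):
        with pytest.raises(ValueError):
            derived_metrics(disposition, 0.0)


def test_sampler_kernels_match_reference_solution(disposition, absorption):
    """The compiled hot-loop kernels and their pure-Python fallback both
    reproduce the vectorized closed-form concentrations."""
    from vitapk import _kernels

    times = np.array([0.5, 2.0, 3.76, 6.0, 24.0, 48.0])
    args = (
        absorption.ka, absorption.Tk0, absorption.Fr,
        disposition.V1, disposition.V2, disposition.Q, disposition.CL,
        absorption.F,
        times, np.array([0.0]), np.array([DOSE]), np.array([True]),
    )
    ref = conc_oral_mixed(disposition, absorption, DOSE, times)
    np.testing.assert_allclose(_kernels.occ_conc(*args), ref, rtol=1e-12)
    np.testing.assert_allclose(_kernels._occ_conc_impl(*args), ref, rtol=1e-12)


def test_profile_length_mismatch_rejected():
    with pytest.raises(ValueError):
        ConcentrationProfile(np.array([0.0, 1.0]), np.array([1.0]))
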