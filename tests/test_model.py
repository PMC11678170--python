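"""Structural model: parameters, closed-form PK, ODE routes, utilities."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sckmipd.errors import CalibrationError, InvalidInputError, SimulationError
from sckmipd.model import (
    DoseEvent,
    PDParameters,
    PKParameters,
    calibrate_q_to_half_life,
    inhibition_multiplier,
    initial_state,
    scale_pk_allometric,
    simulate,
    simulate_states,
    terminal_half_life,
    trough_concentration,
)


def make_pk(**over):
    base = dict(ka=0.18, F=0.73, CL=0.19, V2=3.61, V3=2.87, Q=0.3)
    base.update(over)
    return PKParameters(**base)


def make_pd(**over):
    base = dict(kout=0.11, Imax=1.19, IC50=9.35, koutTOL=0.003, PASI_base=11.6, SLP=0.0)
    base.update(over)
    return PDParameters(**base)


class TestParameterValidation:
    @pytest.mark.parametrize("field", ["ka", "F", "V2", "V3", "Q"])
    def test_pk_strictly_positive(self, field):
        with pytest.raises(InvalidInputError):
            make_pk(**{field: 0.0})
        with pytest.raises(InvalidInputError):
            make_pk(**{field: -1.0})

    def test_cl_zero_allowed_negative_not(self):
        assert make_pk(CL=0.0).CL == 0.0
        with pytest.raises(InvalidInputError):
            make_pk(CL=-0.1)

    def test_bioavailability_bounded(self):
        with pytest.raises(InvalidInputError):
            make_pk(F=1.2)

    @pytest.mark.parametrize(
        "field,value",
        [("kout", 0.0), ("IC50", -1.0), ("Imax", -0.1), ("SLP", -1e-6),
         ("koutTOL", 0.0), ("PASI_base", -0.5)],
    )
    def test_pd_validation(self, field, value):
        with pytest.raises(InvalidInputError):
            make_pd(**{field: value})

    def test_kin_ktr_derived(self):
        pd = make_pd(kout=0.11, PASI_base=10.0)
        assert pd.kin == pytest.approx(1.1)
        assert pd.ktr == pd.kout

    def test_dose_event_validation(self):
        with pytest.raises(InvalidInputError):
            DoseEvent(time=-1.0, amount=300.0)
        with pytest.raises(InvalidInputError):
            DoseEvent(time=0.0, amount=-5.0)
        with pytest.raises(InvalidInputError):
            DoseEvent(time=0.0, amount=300.0, route="IV")


class TestAllometry:
    def test_reference_weight_identity(self):
        pk = make_pk()
        assert scale_pk_allometric(pk, 70.0) == pk

    def test_scaling_formula(self):
        pk = make_pk()
        s = scale_pk_allometric(pk, 97.0, 70.0, 0.8, 1.0)
        assert s.CL == pytest.approx(0.19 * (97.0 / 70.0) ** 0.8)
        assert s.V2 == pytest.approx(3.61 * 97.0 / 70.0)
        assert (s.ka, s.F, s.V3, s.Q) == (pk.ka, pk.F, pk.V3, pk.Q)

    def test_invalid_weight(self):
        with pytest.raises(InvalidInputError):
            scale_pk_allometric(make_pk(), -5.0)


class TestHalfLife:
    def test_eigenvalue_oracle(self):
        pk = make_pk(Q=0.30327)
        k10, k12, k21 = pk.CL / pk.V2, pk.Q / pk.V2, pk.Q / pk.V3
        A = np.array([[-(k10 + k12), k21], [k12, -k21]])
        beta = -np.max(np.linalg.eigvals(A).real)
        assert terminal_half_life(pk) == pytest.approx(math.log(2.0) / beta, rel=1e-12)

    def test_calibration_roundtrip(self):
        q = calibrate_q_to_half_life(0.19, 3.61, 2.87, 27.0)
        pk = make_pk(Q=q)
        assert terminal_half_life(pk) == pytest.approx(27.0, rel=1e-8)

    def test_infeasible_target(self):
        limit = math.log(2.0) * (3.61 + 2.87) / 0.19
        with pytest.raises(CalibrationError):
            calibrate_q_to_half_life(0.19, 3.61, 2.87, 0.9 * limit)

    def test_undefined_without_elimination(self):
        with pytest.raises(InvalidInputError):
            terminal_half_life(make_pk(CL=0.0))
        with pytest.raises(CalibrationError):
            calibrate_q_to_half_life(0.0, 3.61, 2.87, 27.0)


class TestInhibition:
    def test_zero_concentration(self):
        assert inhibition_multiplier(0.0, 1.19, 9.35) == 1.0

    def test_half_maximal(self):
        assert inhibition_multiplier(9.35, 1.19, 9.35) == pytest.approx(1.0 - 1.19 / 2.0)

    def test_floor_when_imax_exceeds_one(self):
        assert inhibition_multiplier(1e6, 1.19, 9.35) == 0.0

    def test_tolerance_attenuates(self):
        full = inhibition_multiplier(50.0, 1.19, 9.35, M3=0.0)
        tol = inhibition_multiplier(50.0, 1.19, 9.35, M3=2.0)
        assert tol > full

    def test_negative_concentration(self):
        with pytest.raises(InvalidInputError):
            inhibition_multiplier(-1.0, 1.19, 9.35)


class TestSimulate:
    def test_input_validation(self):
        psi = (make_pk(), make_pd())
        with pytest.raises(InvalidInputError):
            simulate(psi, [], [])
        with pytest.raises(InvalidInputError):
            simulate(psi, [], [2.0, 1.0])
        with pytest.raises(InvalidInputError):
            simulate(psi, [DoseEvent(10.0, 300.0), DoseEvent(0.0, 300.0)], [1.0])
        with pytest.raises(InvalidInputError):
            simulate(psi, [], [1.0], method="euler")

    def test_terminal_slope_matches_half_life(self):
        pk = make_pk(Q=calibrate_q_to_half_life(0.19, 3.61, 2.87, 27.0))
        psi = (pk, make_pd())
        t = np.array([300.0, 340.0])
        traj = simulate(psi, [DoseEvent(0.0, 300.0)], t)
        slope = -np.diff(np.log(traj.conc))[0] / 40.0
        assert slope == pytest.approx(math.log(2.0) / 27.0, rel=1e-4)

    def test_routes_agree(self):
        psi = (make_pk(), make_pd())
        doses = [DoseEvent(0.0, 300.0), DoseEvent(28.0, 300.0)]
        t = np.linspace(1.0, 100.0, 34)
        rk4 = simulate(psi, doses, t, method="rk4", dt_max=0.1)
        lsoda = simulate(psi, doses, t, method="lsoda")
        ode = simulate(psi, doses, t, method="ode")
        assert np.allclose(rk4.pasi, lsoda.pasi, rtol=1e-4, atol=1e-6)
        assert np.allclose(rk4.pasi, ode.pasi, rtol=1e-4, atol=1e-6)
        assert np.allclose(rk4.conc, ode.conc, rtol=1e-5, atol=1e-8)

    def test_pasi_declines_under_treatment(self):
        psi = (make_pk(), make_pd())
        doses = [DoseEvent(28.0 * k, 300.0) for k in range(10)]
        traj = simulate(psi, doses, np.array([30.0, 90.0, 200.0]))
        assert traj.pasi[0] < 11.6
        assert traj.pasi[2] < traj.pasi[0]

    def test_tolerance_state_grows_only_when_enabled(self):
        doses = [DoseEvent(28.0 * k, 300.0) for k in range(10)]
        t = np.array([100.0, 250.0])
        off = simulate((make_pk(), make_pd(SLP=0.0)), doses, t)
        on = simulate((make_pk(), make_pd(SLP=5e-4)), doses, t)
        assert np.all(off.tolerance == 0.0)
        assert on.tolerance[1] > on.tolerance[0] > 0.0
        assert on.pasi[1] > off.pasi[1]

    @given(st.floats(min_value=0.0, max_value=72.0))
    def test_stationarity_without_drug(self, base):
        psi = (make_pk(), make_pd(PASI_base=base))
        traj = simulate(psi, [], np.array([10.0, 365.0]))
        assert np.allclose(traj.pasi, base, rtol=1e-9, atol=1e-9)
        assert np.all(traj.conc == 0.0)

    @given(st.floats(min_value=50.0, max_value=600.0))
    def test_concentration_scales_linearly_with_dose(self, amount):
        pk = make_pk()
        doses1 = [DoseEvent(0.0, amount)]
        doses2 = [DoseEvent(0.0, 2.0 * amount)]
        t = np.array([5.0, 40.0])
        c1 = simulate((pk, make_pd()), doses1, t).conc
        c2 = simulate((pk, make_pd()), doses2, t).conc
        assert np.allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_initial_state_fields(self):
        s = initial_state(7.5)
        assert s.PASI == s.P1 == s.P2 == s.P3 == s.P4 == 7.5
        assert s.A_depot == s.A_c == s.M3 == 0.0
        with pytest.raises(InvalidInputError):
            initial_state(-1.0)


class TestSimulateStates:
    def test_shapes_and_baseline(self):
        psi = (make_pk(), make_pd())
        t, states = simulate_states(psi, [DoseEvent(0.0, 300.0)], np.array([0.0, 10.0]))
        assert states.shape == (2, 11)
        # at t=0 the dose sits in the depot and PASI is at baseline
        assert states[0, 0] == pytest.approx(0.73 * 300.0)
        assert states[0, 7] == pytest.approx(11.6)


class TestTrough:
    def test_interpolated_trough(self):
        from sckmipd.mipd import Regimen, regimen_doses

        reg = Regimen(300.0, 4)
        psi = (make_pk(), make_pd())
        t = np.linspace(0.5, 300.0, 600)
        traj = simulate(psi, regimen_doses(reg, 10), t)
        v = trough_concentration(traj, reg, 5)
        assert v == pytest.approx(np.interp(5 * 28.0, t, traj.conc))

    def test_beyond_horizon(self):
        from sckmipd.mipd import Regimen

        psi = (make_pk(), make_pd())
        traj = simulate(psi, [DoseEvent(0.0, 300.0)], np.array([1.0, 10.0]))
        with pytest.raises(InvalidInputError):
            trough_concentration(traj, Regimen(300.0, 4), 3)
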