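"""Structural PK/PD model of secukinumab in plaque psoriasis.

PK: two-compartment disposition with first-order subcutaneous absorption
(depot -> central <-> peripheral), linear clearance from the central
compartment, serum concentration C = A_c / V2.

PD: indirect-response turnover of the PASI severity score.  Drug inhibits
the zero-order lesion production rate ``kin`` through an Imax model; a
chain of four prePASI transit compartments delays the observable response;
three mediator compartments driven linearly by concentration (slope SLP)
build up a tolerance signal M3 that attenuates the inhibition.

All times are in days, amounts in mg, concentrations in mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _kernel
from .errors import CalibrationError, InvalidInputError, SimulationError

__all__ = [
    "PKParameters",
    "PDParameters",
    "StateVector",
    "DoseEvent",
    "Trajectory",
    "scale_pk_allometric",
    "terminal_half_life",
    "calibrate_q_to_half_life",
    "inhibition_multiplier",
    "initial_state",
    "simulate",
    "simulate_states",
    "trough_concentration",
]


@dataclass(frozen=True)
class PKParameters:
    """Individual or typical PK parameter set.

    ka: first-order absorption rate (1/day); F: absolute bioavailability;
    CL: clearance (L/day); V2/V3: central/peripheral volumes (L);
    Q: intercompartmental clearance (L/day).
    """

    ka: float
    F: float
    CL: float
    V2: float
    V3: float
    Q: float

    def __post_init__(self):
        for name in ("ka", "F", "V2", "V3", "Q"):
            v = getattr(self, name)
            if not (v > 0.0) or not math.isfinite(v):
                raise InvalidInputError(f"PKParameters.{name} must be strictly positive, got {v}")
        # CL = 0 (no elimination) is admitted for conservation checks
        if not (self.CL >= 0.0) or not math.isfinite(self.CL):
            raise InvalidInputError(f"PKParameters.CL must be >= 0, got {self.CL}")
        if self.F > 1.0:
            raise InvalidInputError(f"bioavailability F must be <= 1, got {self.F}")


@dataclass(frozen=True)
class PDParameters:
    """Individual or typical PD parameter set.

    kout: first-order lesion remission rate (1/day); Imax: maximum
    inhibition (may exceed 1; the production term is floored at zero);
    IC50: concentration of half-maximal inhibition (mg/L); SLP: linear
    tolerance-driving slope (L/mg/day); koutTOL: tolerance mediator
    turnover rate (1/day); PASI_base: individual baseline PASI.

    kin (lesion production, PASI/day) is derived as kout * PASI_base so
    that the pre-treatment state is exactly stationary.
    """

    kout: float
    Imax: float
    IC50: float
    koutTOL: float
    PASI_base: float
    SLP: float = 0.0

    def __post_init__(self):
        if not self.kout > 0.0:
            raise InvalidInputError(f"kout must be > 0, got {self.kout}")
        if not self.IC50 > 0.0:
            raise InvalidInputError(f"IC50 must be > 0, got {self.IC50}")
        if self.Imax < 0.0:
            raise InvalidInputError(f"Imax must be >= 0, got {self.Imax}")
        if self.SLP < 0.0:
            raise InvalidInputError(f"SLP must be >= 0, got {self.SLP}")
        if not self.koutTOL > 0.0:
            raise InvalidInputError(f"koutTOL must be > 0, got {self.koutTOL}")
        if self.PASI_base < 0.0:
            raise InvalidInputError(f"PASI_base must be >= 0, got {self.PASI_base}")

    @property
    def kin(self) -> float:
        """Zero-order lesion production rate implied by stationarity."""
        return self.kout * self.PASI_base

    @property
    def ktr(self) -> float:
        """Transit rate of the prePASI chain (tied to kout, see docs)."""
        return self.kout


@dataclass(frozen=True)
class DoseEvent:
    """A subcutaneous bolus administration."""

    time: float
    amount: float
    route: str = "SC"

    def __post_init__(self):
        if self.time < 0.0:
            raise InvalidInputError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0.0:
            raise InvalidInputError(f"dose amount must be >= 0, got {self.amount}")
        if self.route != "SC":
            raise InvalidInputError(f"only SC administration is modelled, got {self.route!r}")


@dataclass(frozen=True)
class StateVector:
    """Full model state: drug amounts, prePASI chain, PASI, mediators."""

    A_depot: float = 0.0
    A_c: float = 0.0
    A_p: float = 0.0
    P1: float = 0.0
    P2: float = 0.0
    P3: float = 0.0
    P4: float = 0.0
    PASI: float = 0.0
    M1: float = 0.0
    M2: float = 0.0
    M3: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.A_depot, self.A_c, self.A_p, self.P1, self.P2, self.P3, self.P4,
             self.PASI, self.M1, self.M2, self.M3]
        )

    def pd_array(self) -> np.ndarray:
        return np.array([self.P1, self.P2, self.P3, self.P4, self.PASI, self.M1, self.M2, self.M3])


@dataclass
class Trajectory:
    """Simulated concentration / PASI / tolerance time courses."""

    times: np.ndarray
    conc: np.ndarray
    pasi: np.ndarray
    tolerance: np.ndarray

    def to_frame(self, patient_id=None):
        import pandas as pd

        df = pd.DataFrame(
            {"time": self.times, "conc": self.conc, "pasi": self.pasi, "tol": self.tolerance}
        )
        if patient_id is not None:
            df.insert(0, "id", patient_id)
        return df


def scale_pk_allometric(
    pop_pk: PKParameters,
    weight: float,
    ref_weight: float = 70.0,
    exp_cl: float = 0.8,
    exp_v2: float = 1.0,
) -> PKParameters:
    """Allometric body-weight scaling of CL and V2.

    CL_i = CL * (weight/ref)^exp_cl and V2_i = V2 * (weight/ref)^exp_v2;
    ka, F, V3 and Q are unaffected.
    """
    if not weight > 0.0:
        raise InvalidInputError(f"weight must be > 0, got {weight}")
    if not ref_weight > 0.0:
        raise InvalidInputError(f"ref_weight must be > 0, got {ref_weight}")
    r = weight / ref_weight
    return replace(pop_pk, CL=pop_pk.CL * r**exp_cl, V2=pop_pk.V2 * r**exp_v2)


def _disposition_rates(pk: PKParameters):
    return pk.CL / pk.V2, pk.Q / pk.V2, pk.Q / pk.V3


def terminal_half_life(pk: PKParameters) -> float:
    """Terminal (beta-phase) half-life in days.

    beta is the smaller root of s^2 - (k10+k12+k21) s + k10 k21 = 0, the
    slow eigenvalue of the two-compartment disposition matrix.
    """
    if pk.CL == 0.0:
        raise InvalidInputError("terminal half-life is undefined without elimination (CL=0)")
    k10, k12, k21 = _disposition_rates(pk)
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    beta = 0.5 * (s - disc)
    return math.log(2.0) / beta


def calibrate_q_to_half_life(
    CL: float, V2: float, V3: float, t_half: float, rtol: float = 1e-9
) -> float:
    """Solve for the intercompartmental clearance Q reproducing t_half.

    The terminal half-life decreases monotonically in Q towards the
    one-compartment limit ln2*(V2+V3)/CL; targets at or below that limit
    are infeasible.
    """
    if not CL > 0.0:
        raise CalibrationError("calibration requires CL > 0")
    limit = math.log(2.0) * (V2 + V3) / CL
    if t_half <= limit * (1.0 + 1e-9):
        raise CalibrationError(
            f"target half-life {t_half:.4g} d is infeasible: the infinite-Q limit for "
            f"CL={CL}, V2={V2}, V3={V3} is {limit:.4g} d"
        )

    def f(log_q):
        pk = PKParameters(ka=1.0, F=1.0, CL=CL, V2=V2, V3=V3, Q=math.exp(log_q))
        return terminal_half_life(pk) - t_half

    lo, hi = math.log(1e-8), math.log(1e8)
    log_q = brentq(f, lo, hi, rtol=rtol)
    return math.exp(log_q)


def inhibition_multiplier(C: float, Imax: float, IC50: float, M3: float = 0.0) -> float:
    """Fractional lesion-production multiplier under drug and tolerance.

    Returns max(0, 1 - Imax*C/(IC50+C) * g(M3)) with the saturating
    tolerance attenuation g(M3) = 1/(1+M3).  The floor is active because
    Imax may exceed 1.
    """
    if C < 0.0:
        raise InvalidInputError(f"concentration must be >= 0, got {C}")
    g = 1.0 / (1.0 + M3)
    return max(0.0, 1.0 - (Imax * C / (IC50 + C)) * g)


def initial_state(pasi_base: float) -> StateVector:
    """Pre-treatment stationary state for a given baseline PASI.

    All prePASI compartments and PASI start at the baseline; drug and
    tolerance states start at zero.  Together with kin = kout*PASI_base
    this makes the drug-free system exactly stationary.
    """
    if pasi_base < 0.0:
        raise InvalidInputError(f"baseline PASI must be >= 0, got {pasi_base}")
    return StateVector(
        P1=pasi_base, P2=pasi_base, P3=pasi_base, P4=pasi_base, PASI=pasi_base
    )


def _resolve_params(psi):
    """Accept an (pk, pd) tuple or any object with .pk / .pd attributes."""
    if isinstance(psi, tuple):
        pk, pd = psi
    else:
        pk, pd = psi.pk, psi.pd
    if not isinstance(pk, PKParameters) or not isinstance(pd, PDParameters):
        raise InvalidInputError("psi must provide PKParameters and PDParameters")
    return pk, pd


def _dose_arrays(doses, F):
    times = np.array([d.time for d in doses], dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise InvalidInputError("dose events must be sorted by time")
    amts = np.array([F * d.amount for d in doses], dtype=float)
    return times, amts


def simulate(
    psi,
    doses,
    times,
    method: str = "rk4",
    dt_max: float = 0.25,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate concentration, PASI and tolerance over a time grid.

    psi: IndividualParameters or (PKParameters, PDParameters).
    method "rk4" (default) uses the closed-form PK with the fixed-step
    kernel; "lsoda" integrates the PD states with scipy's stiff-capable
    solver (same closed-form PK forcing); "ode" integrates the full
    eleven-state system numerically, restarting at every dose event —
    kept as an independent numerical route for verification.
    """
    pk, pd = _resolve_params(psi)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidInputError("empty time grid")
    if np.any(times < 0.0) or np.any(np.diff(times) <= 0.0):
        raise InvalidInputError("time grid must be non-negative and strictly increasing")
    dose_t, dose_a = _dose_arrays(doses, pk.F)

    if method == "ode":
        return _simulate_ode(pk, pd, doses, times, rtol, atol)

    profile = _kernel.PKProfile(pk, doses)
    conc = profile.conc(times)
    y0 = initial_state(pd.PASI_base).pd_array()

    if method == "rk4":
        plan = _kernel.IntegrationPlan(profile, times, dt_max)
        states = _kernel.integrate_pd_over_plan(plan, pd, y0)
        pasi = states[:, _kernel.IDX_PASI]
        tol = states[:, _kernel.IDX_M3]
    elif method == "lsoda":

        def rhs(t, y):
            c = profile.conc(t)[0]
            out = np.empty(8)
            _kernel._pd_rhs(y, c, pd.kin, pd.ktr, pd.kout, pd.Imax, pd.IC50, pd.SLP, pd.koutTOL, out)
            return out

        t0, t1 = 0.0, float(times[-1])
        sol = solve_ivp(
            rhs, (t0, t1), y0, method="LSODA", t_eval=times, rtol=rtol, atol=atol, max_step=7.0
        )
        if not sol.success:
            raise SimulationError(f"LSODA failed over [{t0}, {t1}]: {sol.message}")
        pasi = np.clip(sol.y[_kernel.IDX_PASI], 0.0, None)
        tol = np.clip(sol.y[_kernel.IDX_M3], 0.0, None)
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return Trajectory(times=times, conc=conc, pasi=pasi, tolerance=tol)


def _full_rhs(pk: PKParameters, pd: PDParameters):
    k10, k12, k21 = _disposition_rates(pk)

    def rhs(t, y):
        C = y[1] / pk.V2
        if C < 0.0:
            C = 0.0
        out = np.empty(11)
        out[0] = -pk.ka * y[0]
        out[1] = pk.ka * y[0] - (k10 + k12) * y[1] + k21 * y[2]
        out[2] = k12 * y[1] - k21 * y[2]
        _kernel._pd_rhs(y[3:], C, pd.kin, pd.ktr, pd.kout, pd.Imax, pd.IC50, pd.SLP, pd.koutTOL, out[3:])
        return out

    return rhs


def simulate_states(
    psi, doses, times, rtol: float = 1e-10, atol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Full-state numeric simulation (11 states), bolus restarts at doses.

    Returns (times, states) with states of shape (len(times), 11) in the
    StateVector field order.  Used by the verification suite (mass
    balance, cross-checking the closed-form PK route).
    """
    pk, pd = _resolve_params(psi)
    times = np.asarray(times, dtype=float)
    rhs = _full_rhs(pk, pd)
    y = np.zeros(11)
    y[3:8] = pd.PASI_base
    dose_t, dose_a = _dose_arrays(doses, pk.F)
    segments = np.unique(np.concatenate(([0.0], dose_t, times)))
    out = np.empty((times.size, 11))
    want = {round(t, 12): i for i, t in enumerate(times)}
    dose_map = {}
    for tj, aj in zip(dose_t, dose_a):
        dose_map[round(tj, 12)] = dose_map.get(round(tj, 12), 0.0) + aj
    # apply any dose at t=0
    if round(0.0, 12) in dose_map:
        y[0] += dose_map.pop(round(0.0, 12))
    if round(0.0, 12) in want:
        out[want[round(0.0, 12)]] = y
    for a, b in zip(segments[:-1], segments[1:]):
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise SimulationError(f"LSODA failed over [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        key = round(b, 12)
        if key in dose_map:
            y = y.copy()
            y[0] += dose_map.pop(key)
        if key in want:
            out[want[key]] = y
    return times, out


def _simulate_ode(pk, pd, doses, times, rtol, atol) -> Trajectory:
    t, states = simulate_states((pk, pd), doses, times, rtol=max(rtol, 1e-10), atol=max(atol, 1e-12))
    conc = np.clip(states[:, 1] / pk.V2, 0.0, None)
    pasi = np.clip(states[:, 7], 0.0, None)
    tol = np.clip(states[:, 10], 0.0, None)
    return Trajectory(times=t, conc=conc, pasi=pasi, tolerance=tol)


def trough_concentration(traj: Trajectory, regimen, cycle_index: int) -> float:
    """Concentration immediately before the dose opening cycle_index + 1.

    With maintenance doses at 0, tau, 2*tau, ... the trough of cycle k is
    C(k*tau^-); concentration is continuous across a depot bolus, so the
    grid value (or linear interpolant) at k*tau is returned.
    """
    tau = regimen.tau_days if hasattr(regimen, "tau_days") else float(regimen)
    t_trough = cycle_index * tau
    if t_trough > traj.times[-1] + 1e-9:
        raise InvalidInputError(
            f"cycle {cycle_index} trough at day {t_trough} is beyond the simulated horizon "
            f"{traj.times[-1]} d"
        )
    return float(np.interp(t_trough, traj.times, traj.conc))
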