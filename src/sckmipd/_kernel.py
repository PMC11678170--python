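"""Fast numerical kernel for PK/PD trajectory evaluation.

The two-compartment PK subsystem with first-order absorption is linear,
so the serum concentration after any bolus history is a superposition of
tri-exponential unit responses evaluated in closed form.  Only the eight
pharmacodynamic states (four prePASI transit compartments, PASI, three
tolerance mediators) are integrated numerically, with a fixed-step
classical Runge-Kutta scheme whose steps are aligned to dose times (the
concentration forcing is continuous but has derivative kinks there).

Because the PK model carries no random effects beyond body weight, the
concentration forcing is shared by every clone of a patient and by every
iteration of the individual sampler: an integration *plan* (step grid
plus concentration values at the step nodes and midpoints) is built once
and reused.

State layout for the PD vector: [P1, P2, P3, P4, PASI, M1, M2, M3].
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# indices into the PD state vector
IDX_PASI = 4
IDX_M3 = 7
N_PD_STATES = 8


@njit(cache=True)
def disposition_coeffs(ka, CL, V2, V3, Q):
    """Macro-constants of the unit SC bolus response.

    Returns (alpha, beta, A1, A2, A3, ka_eff) such that the central amount
    after a unit amount placed in the depot at t=0 is
    ka_eff*(A1*exp(-alpha*t) + A2*exp(-beta*t) + A3*exp(-ka_eff*t)).
    ka is nudged infinitesimally if it collides with a disposition rate.
    """
    k10 = CL / V2
    k12 = Q / V2
    k21 = Q / V3
    s = k10 + k12 + k21
    disc2 = s * s - 4.0 * k10 * k21
    if disc2 < 0.0:
        disc2 = 0.0
    disc = np.sqrt(disc2)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    ka_eff = ka
    eps = 1e-10 * (1.0 + alpha)
    if abs(ka_eff - alpha) < eps or abs(ka_eff - beta) < eps or abs(alpha - beta) < eps:
        ka_eff = ka * (1.0 + 1e-8) + 1e-12
    A1 = (k21 - alpha) / ((ka_eff - alpha) * (beta - alpha))
    A2 = (k21 - beta) / ((ka_eff - beta) * (alpha - beta))
    A3 = (k21 - ka_eff) / ((alpha - ka_eff) * (beta - ka_eff))
    return alpha, beta, A1, A2, A3, ka_eff


class PKProfile:
    """Closed-form concentration function for one subject's dose history."""

    __slots__ = ("dose_t", "dose_aeff", "V2", "alpha", "beta", "A1", "A2", "A3", "ka_eff")

    def __init__(self, pk, doses):
        self.dose_t = np.array([d.time for d in doses], dtype=float)
        self.dose_aeff = np.array([pk.F * d.amount for d in doses], dtype=float)
        self.V2 = pk.V2
        (self.alpha, self.beta, self.A1, self.A2, self.A3, self.ka_eff) = disposition_coeffs(
            pk.ka, pk.CL, pk.V2, pk.V3, pk.Q
        )

    def conc(self, times) -> np.ndarray:
        """Vectorised concentration (mg/L) at arbitrary times."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if self.dose_t.size == 0:
            return np.zeros(t.shape)
        dt = t[:, None] - self.dose_t[None, :]
        live = dt >= 0.0
        dt = np.where(live, dt, 0.0)
        resp = (
            self.A1 * np.exp(-self.alpha * dt)
            + self.A2 * np.exp(-self.beta * dt)
            + self.A3 * np.exp(-self.ka_eff * dt)
        )
        c = (resp * live * self.dose_aeff[None, :]).sum(axis=1) * self.ka_eff / self.V2
        return np.clip(c, 0.0, None)


class IntegrationPlan:
    """Precomputed RK4 step grid and concentration forcing.

    Built from the union of the origin, dose times and evaluation times;
    each inter-breakpoint span is subdivided into steps of at most dt_max.
    rec_slot[i] >= 0 marks that the state after step i must be written to
    that output slot; slot 0 may be the origin itself (eval0).
    """

    __slots__ = ("h", "c0", "ch", "c1", "rec_slot", "n_eval", "eval0", "eval_times")

    def __init__(self, profile: PKProfile, eval_times, dt_max: float, t_origin: float = 0.0):
        eval_times = np.unique(np.asarray(eval_times, dtype=float))
        pts = np.unique(np.concatenate(([t_origin], profile.dose_t, eval_times)))
        pts = pts[pts >= t_origin]
        is_eval = np.isin(pts, eval_times)
        starts, hs, rec = [], [], []
        self.eval0 = bool(is_eval[0])
        slot = 1 if self.eval0 else 0
        for i in range(pts.size - 1):
            a, b = pts[i], pts[i + 1]
            n = max(1, int(math.ceil((b - a) / dt_max)))
            h = (b - a) / n
            for k in range(n):
                starts.append(a + k * h)
                hs.append(h)
                rec.append(-1)
            if is_eval[i + 1]:
                rec[-1] = slot
                slot += 1
        self.n_eval = slot
        self.h = np.asarray(hs)
        self.rec_slot = np.asarray(rec, dtype=np.int64)
        st = np.asarray(starts)
        self.c0 = profile.conc(st)
        self.ch = profile.conc(st + 0.5 * self.h)
        self.c1 = profile.conc(st + self.h)
        self.eval_times = eval_times


@njit(cache=True)
def _pd_rhs(y, C, kin, ktr, kout, Imax, IC50, SLP, koutTOL, out):
    g = 1.0 / (1.0 + y[7])
    inh = 1.0 - (Imax * C / (IC50 + C)) * g
    if inh < 0.0:
        inh = 0.0
    out[0] = kin * inh - ktr * y[0]
    out[1] = ktr * (y[0] - y[1])
    out[2] = ktr * (y[1] - y[2])
    out[3] = ktr * (y[2] - y[3])
    out[4] = ktr * y[3] - kout * y[4]
    out[5] = SLP * C - koutTOL * y[5]
    out[6] = koutTOL * (y[5] - y[6])
    out[7] = koutTOL * (y[6] - y[7])


@njit(cache=True)
def rk4_plan(
    h_arr, c0_arr, ch_arr, c1_arr, rec_slot, n_eval, eval0,
    kin, ktr, kout, Imax, IC50, SLP, koutTOL, y0,
):
    """RK4 over a precomputed plan; returns (n_eval, 8) PD states."""
    out = np.empty((n_eval, N_PD_STATES))
    y = y0.copy()
    k1 = np.empty(N_PD_STATES)
    k2 = np.empty(N_PD_STATES)
    k3 = np.empty(N_PD_STATES)
    k4 = np.empty(N_PD_STATES)
    ytmp = np.empty(N_PD_STATES)
    if eval0:
        out[0] = y
    for i in range(h_arr.shape[0]):
        h = h_arr[i]
        _pd_rhs(y, c0_arr[i], kin, ktr, kout, Imax, IC50, SLP, koutTOL, k1)
        for j in range(N_PD_STATES):
            ytmp[j] = y[j] + 0.5 * h * k1[j]
        _pd_rhs(ytmp, ch_arr[i], kin, ktr, kout, Imax, IC50, SLP, koutTOL, k2)
        for j in range(N_PD_STATES):
            ytmp[j] = y[j] + 0.5 * h * k2[j]
        _pd_rhs(ytmp, ch_arr[i], kin, ktr, kout, Imax, IC50, SLP, koutTOL, k3)
        for j in range(N_PD_STATES):
            ytmp[j] = y[j] + h * k3[j]
        _pd_rhs(ytmp, c1_arr[i], kin, ktr, kout, Imax, IC50, SLP, koutTOL, k4)
        for j in range(N_PD_STATES):
            y[j] += h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if y[j] < 0.0:
                y[j] = 0.0
        s = rec_slot[i]
        if s >= 0:
            out[s] = y
    return out


@njit(cache=True)
def rk4_plan_batch(
    h_arr, c0_arr, ch_arr, c1_arr, rec_slot, n_eval, eval0,
    kin_a, ktr_a, kout_a, Imax_a, IC50_a, SLP_a, koutTOL_a, y0_a,
):
    """Clone loop over a shared plan; returns (n_clones, n_eval, 8)."""
    n_clones = kin_a.shape[0]
    out = np.empty((n_clones, n_eval, N_PD_STATES))
    for c in range(n_clones):
        out[c] = rk4_plan(
            h_arr, c0_arr, ch_arr, c1_arr, rec_slot, n_eval, eval0,
            kin_a[c], ktr_a[c], kout_a[c], Imax_a[c], IC50_a[c], SLP_a[c], koutTOL_a[c], y0_a[c],
        )
    return out


def integrate_pd_over_plan(plan: IntegrationPlan, pd, y0) -> np.ndarray:
    """Single-subject convenience wrapper around rk4_plan."""
    return rk4_plan(
        plan.h, plan.c0, plan.ch, plan.c1, plan.rec_slot, plan.n_eval, plan.eval0,
        pd.kin, pd.ktr, pd.kout, pd.Imax, pd.IC50, pd.SLP, pd.koutTOL, y0,
    )
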