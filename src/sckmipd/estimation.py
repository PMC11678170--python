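"""Individual-level Bayesian estimation.

Given a subject's dosing history, sparse concentration and PASI records
and the population model as prior, this module evaluates the individual
log-likelihood, finds the MAP estimate of the random effects, and samples
the conditional (posterior) distribution p(psi_i | y_i) with a random-walk
Metropolis-Hastings algorithm operating on the log-scale random effects.

Because the PK model carries no random effects beyond body weight, the
concentration predictions are fixed given the dosing history; only the
PASI predictions change along the chain, which keeps each posterior
evaluation to a single PD integration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from . import _kernel, model
from .errors import EstimationError, InvalidInputError, SamplerError
from .population import IndividualParameters, PopulationModel, individual_from_etas

__all__ = [
    "Record",
    "ObservationSet",
    "ConditionalSample",
    "log_likelihood",
    "log_prior",
    "map_estimate",
    "sample_conditional",
]

_FAIL_SCORE = -1e10
_LOG_PRED_FLOOR = 1e-10


@dataclass(frozen=True)
class Record:
    """One observation: time (day), kind 'pk'|'pasi', value, censored."""

    time: float
    kind: str
    value: float
    censored: bool = False

    def __post_init__(self):
        if self.time < 0.0:
            raise InvalidInputError(f"record time must be >= 0, got {self.time}")
        if self.kind not in ("pk", "pasi"):
            raise InvalidInputError(f"record kind must be 'pk' or 'pasi', got {self.kind!r}")


@dataclass
class ObservationSet:
    """A subject's TDM data: records, dosing history, covariates."""

    patient_id: str
    records: list
    doses: list
    weight: float
    pasi_obs0: float
    tolerance_active: bool = False

    def by_kind(self, kind):
        return [r for r in self.records if r.kind == kind]


@dataclass
class ConditionalSample:
    """Draws from p(psi_i | y_i) plus chain diagnostics."""

    draws: list  # IndividualParameters, length n_clones
    etas: np.ndarray  # (n_clones, n_params)
    param_names: tuple
    acceptance_rate: float
    seed: object
    ess: dict

    def eta_column(self, name):
        return self.etas[:, self.param_names.index(name)]

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, d in enumerate(self.draws):
            row = {"clone": i, "kout": d.pd.kout, "Imax": d.pd.Imax,
                   "koutTOL": d.pd.koutTOL, "PASI_base": d.pd.PASI_base}
            row.update({f"eta_{k}": v for k, v in d.etas.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _free_eta_names(obs: ObservationSet, free_etas=None):
    if free_etas is not None:
        return tuple(free_etas)
    names = ["kout", "Imax", "RV"]
    if obs.tolerance_active:
        names.append("koutTOL")
    return tuple(names)


def _omega_for(pop: PopulationModel, name: str) -> float:
    if name == "RV":
        return pop.sigma_pasi
    try:
        return pop.omega[name]
    except KeyError:
        raise InvalidInputError(f"no IIV standard deviation configured for eta '{name}'")


class _LikelihoodContext:
    """Precomputed per-subject quantities for fast posterior evaluation."""

    def __init__(self, obs: ObservationSet, pop: PopulationModel, dt_max: float = 0.5):
        self.obs = obs
        self.pop = pop
        self.spec = pop.obs_spec
        self.dt_max = dt_max
        pk = model.scale_pk_allometric(
            pop.pk_typical, obs.weight, pop.ref_weight, pop.exp_cl, pop.exp_v2
        )
        self.pk = pk
        self.profile = _kernel.PKProfile(pk, obs.doses)
        pk_recs = obs.by_kind("pk")
        self.pk_values = np.array([r.value for r in pk_recs])
        self.pk_cens = np.array([r.censored for r in pk_recs], dtype=bool)
        self.pk_pred = self.profile.conc([r.time for r in pk_recs]) if pk_recs else np.empty(0)
        pasi_recs = obs.by_kind("pasi")
        self.pasi_times = np.array(sorted({r.time for r in pasi_recs}))
        self._pasi_idx = np.searchsorted(self.pasi_times, [r.time for r in pasi_recs])
        self.pasi_values = np.array([r.value for r in pasi_recs])
        self.pasi_cens = np.array([r.censored for r in pasi_recs], dtype=bool)
        self._pasi_unc = ~self.pasi_cens
        vals_unc = np.maximum(self.pasi_values[self._pasi_unc], _LOG_PRED_FLOOR)
        self._log_vals_unc = np.log(vals_unc)
        self._unc_const = float(
            -np.sum(self._log_vals_unc)
            - vals_unc.size * math.log(pop.sigma_pasi * math.sqrt(2.0 * math.pi))
        )
        if self.pasi_times.size:
            self.plan = _kernel.IntegrationPlan(self.profile, self.pasi_times, dt_max)
        # PK likelihood does not depend on the PD random effects
        self.pk_loglik_const = self._pk_loglik()

    def _pk_loglik(self) -> float:
        if self.pk_values.size == 0:
            return 0.0
        sd = self.pop.sigma_pk * np.maximum(self.pk_pred, 1e-6)
        ll = 0.0
        for v, c, p, s in zip(self.pk_values, self.pk_cens, self.pk_pred, sd):
            if c:
                # censored below LLOQ or above ULOQ, decided by the recorded value
                if v >= self.spec.uloq_pk:
                    ll += norm.logsf((self.spec.uloq_pk - p) / s)
                else:
                    ll += norm.logcdf((self.spec.lloq_pk - p) / s)
            else:
                ll += norm.logpdf(v, loc=p, scale=s)
        return float(ll)

    def pasi_predictions(self, pd: model.PDParameters) -> np.ndarray:
        y0 = model.initial_state(pd.PASI_base).pd_array()
        states = _kernel.integrate_pd_over_plan(self.plan, pd, y0)
        return states[self._pasi_idx, _kernel.IDX_PASI]

    def loglik(self, psi: IndividualParameters) -> float:
        ll = self.pk_loglik_const
        if self.pasi_values.size == 0:
            return ll
        pred = self.pasi_predictions(psi.pd)
        if not np.all(np.isfinite(pred)):
            return _FAIL_SCORE
        pred = np.maximum(pred, _LOG_PRED_FLOOR)
        sig = self.pop.sigma_pasi
        log_pred = np.log(pred)
        if self.pasi_cens.any():
            z = (math.log(self.spec.pasi_zero_threshold) - log_pred[self.pasi_cens]) / sig
            ll += float(np.sum(norm.logcdf(z)))
        if self._log_vals_unc.size:
            resid = self._log_vals_unc - log_pred[self._pasi_unc]
            ll += self._unc_const - float(resid @ resid) / (2.0 * sig * sig)
        return float(ll)


def log_likelihood(psi: IndividualParameters, obs: ObservationSet, pop: PopulationModel) -> float:
    """Log-likelihood of a subject's records under individual parameters.

    PASI records use the exponential (log-normal) error model, PK records
    the proportional model; censored records contribute the log-CDF below
    their threshold.  Returns a large negative surrogate if the
    simulation produced non-finite predictions.
    """
    if len(obs.records) == 0:
        warnings.warn("empty observation set: log-likelihood is 0", stacklevel=2)
        return 0.0
    return _LikelihoodContext(obs, pop).loglik(psi)


def log_prior(psi: IndividualParameters, pop: PopulationModel) -> float:
    """Log-density of the random effects under the population prior."""
    lp = 0.0
    for name, eta in psi.etas.items():
        if name == "RV":
            w = pop.sigma_pasi
        elif name in pop.omega:
            w = pop.omega[name]
        elif eta != 0.0:
            raise InvalidInputError(f"eta '{name}' is nonzero but has no configured omega")
        else:
            continue
        if w == 0.0:
            if eta != 0.0:
                raise InvalidInputError(f"eta '{name}' nonzero with omega 0")
            continue
        lp += -math.log(w * math.sqrt(2.0 * math.pi)) - eta**2 / (2.0 * w**2)
    return lp


def _make_logpost(obs, pop, names, dt_max=0.5):
    ctx = _LikelihoodContext(obs, pop, dt_max=dt_max)
    omegas = np.array([_omega_for(pop, n) for n in names])
    prior_const = -np.sum(np.log(omegas * math.sqrt(2.0 * math.pi)))

    def logpost(eta_vec):
        etas = dict(zip(names, eta_vec))
        psi = individual_from_etas(pop, obs.weight, obs.pasi_obs0, etas, obs.tolerance_active)
        lp = prior_const - float(np.sum(eta_vec**2 / (2.0 * omegas**2)))
        return ctx.loglik(psi) + lp

    return logpost, omegas


def map_estimate(
    obs: ObservationSet,
    pop: PopulationModel,
    free_etas=None,
    dt_max: float = 0.5,
    maxiter: int = 400,
) -> IndividualParameters:
    """Posterior-mode (MAP) estimate of the random effects.

    Runs a derivative-free optimisation from three starts (prior mode and
    +/- 0.5 omega on every component) and keeps the best objective.
    """
    names = _free_eta_names(obs, free_etas)
    if len(obs.records) == 0:
        return individual_from_etas(
            pop, obs.weight, obs.pasi_obs0, {n: 0.0 for n in names}, obs.tolerance_active
        )
    logpost, omegas = _make_logpost(obs, pop, names, dt_max)
    starts = [np.zeros(len(names)), 0.5 * omegas, -0.5 * omegas]
    best = None
    for x0 in starts:
        try:
            res = minimize(
                lambda x: -logpost(x), x0, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6},
            )
        except Exception:
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise EstimationError(f"all optimisation starts failed for {obs.patient_id}")
    etas = dict(zip(names, best.x))
    return individual_from_etas(pop, obs.weight, obs.pasi_obs0, etas, obs.tolerance_active)


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelations."""
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] < 0.05:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def sample_conditional(
    obs: ObservationSet,
    pop: PopulationModel,
    n_clones: int = 100,
    seed=None,
    free_etas=None,
    n_burn: int = 1000,
    n_keep: int = 5000,
    dt_max: float = 0.5,
    logpost_offset: float = 0.0,
) -> ConditionalSample:
    """Sample the individual conditional distribution by Metropolis-Hastings.

    Random-walk proposals on the eta vector; the proposal scale is adapted
    during burn-in towards a 20-40% acceptance rate, then frozen.  The
    kept iterations are thinned to exactly n_clones draws.  With zero
    observations the conditional equals the prior and exact i.i.d. prior
    draws are returned.  logpost_offset adds a constant to the
    log-posterior (it must not change the chain; exposed for testing the
    normalising-constant invariance).
    """
    if n_clones < 1:
        raise InvalidInputError("n_clones must be >= 1")
    names = _free_eta_names(obs, free_etas)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    omegas = np.array([_omega_for(pop, n) for n in names])

    if len(obs.records) == 0:
        etas = rng.normal(0.0, omegas, size=(n_clones, len(names)))
        draws = [
            individual_from_etas(pop, obs.weight, obs.pasi_obs0, dict(zip(names, e)),
                                 obs.tolerance_active)
            for e in etas
        ]
        ess = {n: float(n_clones) for n in names}
        return ConditionalSample(draws, etas, names, 1.0, seed, ess)

    logpost, _ = _make_logpost(obs, pop, names, dt_max)

    def lp(x):
        return logpost(x) + logpost_offset

    x = np.zeros(len(names))
    fx = lp(x)
    lam = 0.5
    acc_win = 0
    for i in range(n_burn):
        prop = x + lam * omegas * rng.standard_normal(len(names))
        fp = lp(prop)
        if math.log(rng.uniform()) < fp - fx:
            x, fx = prop, fp
            acc_win += 1
        if (i + 1) % 50 == 0:
            rate = acc_win / 50.0
            if rate < 0.20:
                lam *= 0.7
            elif rate > 0.45:
                lam *= 1.4
            acc_win = 0

    if n_keep < n_clones:
        n_keep = n_clones
    kept = np.empty((n_keep, len(names)))
    n_acc = 0
    for i in range(n_keep):
        prop = x + lam * omegas * rng.standard_normal(len(names))
        fp = lp(prop)
        if math.log(rng.uniform()) < fp - fx:
            x, fx = prop, fp
            n_acc += 1
        kept[i] = x
    acc_rate = n_acc / n_keep
    if acc_rate < 0.01:
        raise SamplerError(
            f"acceptance rate {acc_rate:.3%} after adaptation for {obs.patient_id} "
            f"(scale {lam:.3g})"
        )

    thin = n_keep // n_clones
    etas = kept[thin - 1 :: thin][:n_clones]
    draws = [
        individual_from_etas(pop, obs.weight, obs.pasi_obs0, dict(zip(names, e)),
                             obs.tolerance_active)
        for e in etas
    ]
    ess = {n: _ess(kept[:, j]) for j, n in enumerate(names)}
    return ConditionalSample(draws, etas, names, acc_rate, seed, ess)
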