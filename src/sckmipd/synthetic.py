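"""Virtual cohorts and synthetic TDM datasets.

Generates patients whose covariates, dosing regimens, sampling schedule
and data density mirror the 22-patient secukinumab TDM cohort: body
weight and baseline PASI from truncated normals, a regimen mix dominated
by 300 mg q4w, pre-dose plus ~2/7/14/22/30/40-day PK samples around a
reference steady-state dose, PASI visits at baseline, weeks 5-6, weeks
16-24 and then every six months, and log-normal/proportional residual
noise with assay-range and zero-recording censoring.  True individual
parameters are retained so recovery experiments can score the estimation
machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError
from .estimation import ObservationSet, Record
from .mipd import Regimen, induction_doses, regimen_doses
from .model import DoseEvent, simulate
from .population import (
    PopulationModel,
    apply_residual,
    default_population,
    sample_individual,
)

__all__ = [
    "CohortSpec",
    "SamplingDesign",
    "Patient",
    "ScenarioPreset",
    "generate_cohort",
    "high_responder_spec",
    "simulate_trial",
    "scenario_preset",
    "apply_preset",
]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level covariate and treatment distributions."""

    n_patients: int = 22
    weight_mean: float = 74.5
    weight_sd: float = 15.0
    weight_bounds: tuple = (46.0, 97.0)
    pasi0_mean: float = 11.6
    pasi0_sd: float = 5.8
    pasi0_bounds: tuple = (2.0, 27.5)
    # clinical-practice regimen mix (counts out of 22)
    regimen_counts: tuple = (("300 q4w", 18), ("150 q4w", 2), ("300 q5w", 1), ("300 q6w", 1))
    tolerance_fraction: float = 4.0 / 22.0

    def __post_init__(self):
        if self.n_patients < 1:
            raise InvalidInputError("n_patients must be >= 1")
        for lo, hi in (self.weight_bounds, self.pasi0_bounds):
            if not lo < hi:
                raise InvalidInputError("bounds must be ordered (lo < hi)")
        if not 0.0 <= self.tolerance_fraction <= 1.0:
            raise InvalidInputError("tolerance_fraction must be in [0, 1]")


def high_responder_spec(**overrides) -> CohortSpec:
    """Cohort of mild-baseline, tolerance-free patients.

    Decision-rule directionality is assessed on a cohort whose disease
    burden is low enough that maintained or reduced dosing should keep
    PASI <= 1: baseline PASI centred at 5 within [2, 10] and no
    tolerance-developing subjects, with covariates otherwise as in the
    reference cohort.
    """
    base = dict(
        pasi0_mean=5.0,
        pasi0_sd=2.0,
        pasi0_bounds=(2.0, 10.0),
        tolerance_fraction=0.0,
    )
    base.update(overrides)
    return CohortSpec(**base)


@dataclass(frozen=True)
class SamplingDesign:
    """PK/PASI observation schedule of the TDM study."""

    pk_offsets: tuple = (0.0, 2.0, 7.0, 14.0, 22.0, 30.0, 40.0)
    pasi_window1: tuple = (35.0, 42.0)  # weeks 5-6
    pasi_window2: tuple = (112.0, 168.0)  # weeks 16-24
    pasi_interval: float = 182.0  # every 6 months thereafter
    pasi_jitter: float = 14.0

    def __post_init__(self):
        off = np.asarray(self.pk_offsets)
        if np.any(off < 0) or np.any(np.diff(off) <= 0):
            raise InvalidInputError("pk_offsets must be non-negative and sorted")


@dataclass(frozen=True)
class ScenarioPreset:
    """Population/cohort overrides defining a study scenario."""

    name: str
    kout_typical: float | None = None
    imax_range: tuple | None = None
    tolerance_all: bool = False


def scenario_preset(name: str) -> ScenarioPreset:
    """Named scenarios observed in the cohort analysis.

    'typical' is the fitted population as-is; 'non_responder' lowers the
    typical lesion remission rate to 0.07 /day and activates the
    tolerance mechanism (sustained non-response in the cohort coincided
    with tolerance-flagged patients, with the lower kout as its marker);
    'intensification_candidate' draws individual Imax uniformly in
    [1.06, 1.13]; 'tolerance' activates the tolerance submodel for every
    patient at typical parameters.
    """
    presets = {
        "typical": ScenarioPreset("typical"),
        "non_responder": ScenarioPreset("non_responder", kout_typical=0.07, tolerance_all=True),
        "intensification_candidate": ScenarioPreset(
            "intensification_candidate", imax_range=(1.06, 1.13)
        ),
        "tolerance": ScenarioPreset("tolerance", tolerance_all=True),
    }
    try:
        return presets[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown scenario {name!r}; expected one of {sorted(presets)}"
        )


def apply_preset(pop: PopulationModel, preset: ScenarioPreset) -> PopulationModel:
    """Return the population model with the preset's typical-value overrides."""
    if preset.kout_typical is not None:
        pop = replace(pop, pd_typical=replace(pop.pd_typical, kout=preset.kout_typical))
    return pop


@dataclass
class Patient:
    """A virtual subject with retained ground-truth parameters."""

    patient_id: int
    weight: float
    pasi_obs0: float
    regimen: Regimen
    tolerance_active: bool
    psi_true: object  # IndividualParameters


def _truncnorm(rng, mean, sd, bounds, max_tries=100000):
    """Rejection sampling honouring the bounds exactly."""
    lo, hi = bounds
    if sd == 0.0:
        if not (lo <= mean <= hi):
            raise InvalidInputError("degenerate spec: mean outside bounds with sd=0")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise InvalidInputError("truncated-normal bounds are infeasible for the given mean/sd")


def _regimen_assignment(spec: CohortSpec, rng) -> list:
    labels = []
    total = sum(c for _, c in spec.regimen_counts)
    for label, count in spec.regimen_counts:
        k = int(round(count / total * spec.n_patients))
        labels.extend([label] * k)
    # pad/trim to n with the majority regimen
    majority = max(spec.regimen_counts, key=lambda lc: lc[1])[0]
    while len(labels) < spec.n_patients:
        labels.append(majority)
    labels = labels[: spec.n_patients]
    rng.shuffle(labels)
    return [Regimen.from_label(lab) for lab in labels]


def generate_cohort(
    spec: CohortSpec,
    pop: PopulationModel | None = None,
    preset: ScenarioPreset | None = None,
    seed=None,
) -> list:
    """Draw a virtual cohort with ground-truth individual parameters.

    Returns a list of Patient.  Deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = pop if pop is not None else default_population()
    if preset is not None:
        pop = apply_preset(pop, preset)
    n = spec.n_patients
    regimens = _regimen_assignment(spec, rng)
    if preset is not None and preset.tolerance_all:
        tol_ids = set(range(1, n + 1))
    else:
        k = int(round(spec.tolerance_fraction * n))
        tol_ids = set(rng.choice(np.arange(1, n + 1), size=k, replace=False).tolist())
    patients = []
    for pid in range(1, n + 1):
        weight = _truncnorm(rng, spec.weight_mean, spec.weight_sd, spec.weight_bounds)
        pasi0 = _truncnorm(rng, spec.pasi0_mean, spec.pasi0_sd, spec.pasi0_bounds)
        tol = pid in tol_ids
        psi = sample_individual(pop, weight, pasi0, seed=rng, tolerance_active=tol)
        if preset is not None and preset.imax_range is not None:
            lo, hi = preset.imax_range
            imax = float(rng.uniform(lo, hi))
            eta_imax = math.log(imax / pop.pd_typical.Imax)
            etas = dict(psi.etas)
            etas["Imax"] = eta_imax
            psi = replace(psi, pd=replace(psi.pd, Imax=imax), etas=etas)
        patients.append(
            Patient(
                patient_id=pid,
                weight=weight,
                pasi_obs0=pasi0,
                regimen=regimens[pid - 1],
                tolerance_active=tol,
                psi_true=psi,
            )
        )
    return patients


def _pasi_visit_times(design: SamplingDesign, duration_days: float, rng) -> list:
    times = []
    for lo, hi in (design.pasi_window1, design.pasi_window2):
        t = rng.uniform(lo, hi)
        if t < duration_days:
            times.append(t)
    t = times[-1] if times else 0.0
    while True:
        t = t + design.pasi_interval + rng.uniform(-design.pasi_jitter, design.pasi_jitter)
        if t >= duration_days:
            break
        times.append(t)
    return times


def simulate_trial(
    cohort,
    pop: PopulationModel,
    design: SamplingDesign | None = None,
    duration_years: float = 1.5,
    seed=None,
    induction: bool = False,
) -> list:
    """Simulate the observation process for every cohort patient.

    Each patient is dosed on their maintenance regimen from day 0 (with
    optional weekly induction, which shifts maintenance to start after
    week 4), observed at the design's PK and PASI times, and perturbed
    with residual error, assay-range and zero-recording censoring.
    Returns one ObservationSet per patient.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = design if design is not None else SamplingDesign()
    duration = duration_years * 365.0
    if design.pk_offsets[-1] >= duration or design.pasi_window1[0] >= duration:
        raise InvalidInputError("sampling design extends beyond the trial duration")
    spec = pop.obs_spec
    out = []
    for pat in cohort:
        tau = pat.regimen.tau_days
        if induction:
            start = 28.0 + tau
            n_cycles = int(math.ceil((duration - start) / tau)) + 1
            doses = induction_doses(pat.regimen.dose) + regimen_doses(
                pat.regimen, n_cycles, start=start
            )
        else:
            n_cycles = int(math.ceil(duration / tau)) + 1
            doses = regimen_doses(pat.regimen, n_cycles)
        doses = [d for d in doses if d.time < duration]
        dose_times = np.array([d.time for d in doses])
        # PK samples anchored to the maintenance dose nearest mid-study
        ref = float(dose_times[np.argmin(np.abs(dose_times - 0.5 * duration))])
        pk_times = [ref + o for o in design.pk_offsets if ref + o < duration]
        pasi_times = _pasi_visit_times(design, duration, rng)
        all_times = np.unique(np.array(pk_times + pasi_times))
        traj = simulate(pat.psi_true, doses, all_times)
        conc = dict(zip(all_times, traj.conc))
        pasi = dict(zip(all_times, traj.pasi))
        records = []
        for t in pk_times:
            obs, cens = apply_residual(conc[t], spec, "pk", pop.sigma_pk, rng)
            if cens and obs < spec.lloq_pk:
                obs = 0.0  # BQL: reported value is not quantifiable
            elif obs > spec.uloq_pk:
                obs, cens = spec.uloq_pk, True  # above assay range
            records.append(Record(time=float(t), kind="pk", value=float(obs), censored=cens))
        for t in pasi_times:
            obs, cens = apply_residual(pasi[t], spec, "pasi", pop.sigma_pasi, rng)
            records.append(Record(time=float(t), kind="pasi", value=float(obs), censored=cens))
        records.sort(key=lambda r: (r.time, r.kind))
        out.append(
            ObservationSet(
                patient_id=str(pat.patient_id),
                records=records,
                doses=doses,
                weight=pat.weight,
                pasi_obs0=pat.pasi_obs0,
                tolerance_active=pat.tolerance_active,
            )
        )
    return out
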