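"""Population parameter set, baseline handling and virtual individuals.

The fixed effects, inter-individual variability (IIV) standard deviations
and residual error come from the final population PK/PD analysis of the
secukinumab TDM cohort; the PK disposition parameters come from the
published reference two-compartment model, with body weight acting on CL
(exponent 0.8) and V2 (exponent 1) allometrically.  IIV is log-normal
(p_i = p_typ * exp(eta), eta ~ N(0, omega^2)); PASI residual error is
exponential (log-normal) and PK residual error proportional.

Baseline PASI uses the B2 method: the individual model baseline is the
observed baseline times exp(eta_RV), where the prior SD of eta_RV is
constrained to the residual error SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError
from .model import PDParameters, PKParameters, calibrate_q_to_half_life, scale_pk_allometric

__all__ = [
    "PopulationModel",
    "IndividualParameters",
    "ObservationModelSpec",
    "default_population",
    "sample_individual",
    "b2_baseline",
    "apply_residual",
    "DEFAULT_SLP_TOLERANCE",
]

#: Tolerance-driving slope (L/mg/day) used for tolerance-active patients.
#: Not an estimate from the cohort analysis; calibrated so that a typical
#: tolerance-developing patient on 300 mg q4w relapses to at least half
#: of baseline PASI within a 1.5-year study horizon (secondary loss of
#: response), then rounded up to one significant figure.
#: Config-overridable.
DEFAULT_SLP_TOLERANCE = 5e-4

_REF_HALF_LIFE_DAYS = 27.0


@dataclass(frozen=True)
class ObservationModelSpec:
    """Residual-error forms and assay/recording limits."""

    pasi_error_form: str = "exponential"
    pk_error_form: str = "proportional"
    lloq_pk: float = 0.2
    uloq_pk: float = 225.0
    pasi_zero_threshold: float = 0.05

    def __post_init__(self):
        if not self.lloq_pk < self.uloq_pk:
            raise InvalidInputError("lloq_pk must be below uloq_pk")


@dataclass(frozen=True)
class PopulationModel:
    """Typical values, IIV, residual error and allometric settings."""

    pk_typical: PKParameters
    pd_typical: PDParameters
    omega: dict  # parameter name -> log-scale IIV SD
    sigma_pasi: float  # exponential-scale residual SD
    sigma_pk: float  # proportional residual SD (not reported; assumed)
    ref_weight: float = 70.0
    exp_cl: float = 0.8
    exp_v2: float = 1.0
    obs_spec: ObservationModelSpec = field(default_factory=ObservationModelSpec)
    slp_tolerance: float = DEFAULT_SLP_TOLERANCE

    def __post_init__(self):
        if any(v < 0 for v in self.omega.values()):
            raise InvalidInputError("omega SDs must be >= 0")
        if not self.sigma_pasi > 0:
            raise InvalidInputError("sigma_pasi must be > 0")
        if self.sigma_pk < 0:
            raise InvalidInputError("sigma_pk must be >= 0")


@dataclass(frozen=True)
class IndividualParameters:
    """One subject's realised parameter set (weight-scaled PK, PD, etas)."""

    pk: PKParameters
    pd: PDParameters
    etas: dict
    weight: float
    tolerance_active: bool = False


def default_population() -> PopulationModel:
    """The cohort's population PK/PD model.

    kout 0.11 /day, koutTOL 0.003 /day, Imax 1.19, IC50 9.35 mg/L (fixed);
    IIV SDs 0.913 (kout), 0.3715 (koutTOL), 0.0763 (Imax); PASI residual
    0.76 (exponential).  PK: CL 0.19 L/day, V2 3.61 L, V3 2.87 L with Q
    calibrated so the terminal half-life is 27 days; ka 0.18 /day and
    F 0.73 are reference-model conventions (not re-estimated here).
    """
    CL, V2, V3 = 0.19, 3.61, 2.87
    Q = calibrate_q_to_half_life(CL, V2, V3, _REF_HALF_LIFE_DAYS)
    pk = PKParameters(ka=0.18, F=0.73, CL=CL, V2=V2, V3=V3, Q=Q)
    pd = PDParameters(kout=0.11, Imax=1.19, IC50=9.35, koutTOL=0.003, PASI_base=0.0, SLP=0.0)
    return PopulationModel(
        pk_typical=pk,
        pd_typical=pd,
        omega={"kout": 0.913, "koutTOL": 0.3715, "Imax": 0.0763},
        sigma_pasi=0.76,
        sigma_pk=0.20,
    )


def b2_baseline(pasi_obs0: float, eta_rv: float) -> float:
    """B2 baseline: observed baseline times a log-normal deviate."""
    if pasi_obs0 < 0.0:
        raise InvalidInputError(f"observed baseline PASI must be >= 0, got {pasi_obs0}")
    return pasi_obs0 * float(np.exp(eta_rv))


def individual_from_etas(
    pop: PopulationModel,
    weight: float,
    pasi_obs0: float,
    etas: dict,
    tolerance_active: bool = False,
) -> IndividualParameters:
    """Deterministic construction of an individual from its random effects.

    etas may contain 'kout', 'koutTOL', 'Imax' and 'RV'; missing entries
    default to zero.  The tolerance slope SLP is pop.slp_tolerance for
    flagged subjects and zero otherwise.
    """
    if not (20.0 <= weight <= 200.0):
        raise InvalidInputError(f"weight {weight} kg outside the physiologic range 20-200 kg")
    e = {"kout": 0.0, "koutTOL": 0.0, "Imax": 0.0, "RV": 0.0}
    unknown = set(etas) - set(e)
    if unknown:
        raise InvalidInputError(f"unknown eta names: {sorted(unknown)}")
    e.update(etas)
    pk = scale_pk_allometric(pop.pk_typical, weight, pop.ref_weight, pop.exp_cl, pop.exp_v2)
    t = pop.pd_typical
    pd = PDParameters(
        kout=t.kout * float(np.exp(e["kout"])),
        Imax=t.Imax * float(np.exp(e["Imax"])),
        IC50=t.IC50,
        koutTOL=t.koutTOL * float(np.exp(e["koutTOL"])),
        PASI_base=b2_baseline(pasi_obs0, e["RV"]),
        SLP=pop.slp_tolerance if tolerance_active else 0.0,
    )
    return IndividualParameters(pk=pk, pd=pd, etas=dict(e), weight=weight,
                                tolerance_active=tolerance_active)


def sample_individual(
    pop: PopulationModel,
    weight: float,
    pasi_obs0: float,
    seed=None,
    tolerance_active: bool = False,
) -> IndividualParameters:
    """Draw one virtual individual from the population distribution."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    etas = {
        "kout": rng.normal(0.0, pop.omega["kout"]),
        "koutTOL": rng.normal(0.0, pop.omega["koutTOL"]),
        "Imax": rng.normal(0.0, pop.omega["Imax"]),
        "RV": rng.normal(0.0, pop.sigma_pasi),
    }
    return individual_from_etas(pop, weight, pasi_obs0, etas, tolerance_active)


def apply_residual(pred: float, spec: ObservationModelSpec, kind: str, sigma: float, seed=None):
    """Perturb a model prediction with residual error; apply censoring.

    kind="pasi": obs = pred*exp(eps), eps ~ N(0, sigma^2); observations
    below the recording threshold are recorded as 0 with censored=True.
    kind="pk": obs = pred*(1+eps); non-negative-clipped; values below the
    assay LLOQ are flagged censored (BQL).  Returns (observed, censored).
    """
    if pred < 0.0:
        raise InvalidInputError(f"prediction must be >= 0, got {pred}")
    rng = _as_rng(seed)
    if kind == "pasi":
        obs = pred * float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else pred
        if obs < spec.pasi_zero_threshold:
            return 0.0, True
        return obs, False
    if kind == "pk":
        obs = pred * (1.0 + rng.normal(0.0, sigma)) if sigma > 0 else pred
        obs = max(obs, 0.0)
        if obs < spec.lloq_pk:
            return obs, True
        return obs, False
    raise InvalidInputError(f"unknown observation kind {kind!r}")


def _as_rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
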