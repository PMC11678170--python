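"""Run configuration: population overrides and pipeline settings.

One YAML (or JSON) file drives every stage; all population values default
to the fitted cohort model and may be overridden by name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .errors import InvalidInputError
from .population import PopulationModel, default_population

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class MHSettings:
    n_burn: int = 1000
    n_keep: int = 5000


@dataclass
class MipdSettings:
    n_clones: int = 100
    target: float = 1.0
    prob_rule: float = 90.0
    cycles: tuple = (10, 20)


@dataclass
class CostSettings:
    unit_cost_eur: float = 1246.98
    comparator_doses_per_year: int = 14


#: population keys accepted in the `population:` override block
_PK_KEYS = {"ka", "F", "CL", "V2", "V3", "Q"}
_PD_KEYS = {"kout", "Imax", "IC50", "koutTOL"}
_POP_KEYS = {"sigma_pasi", "sigma_pk", "ref_weight", "exp_cl", "exp_v2", "slp_tolerance"}


@dataclass
class RunConfig:
    population: dict = field(default_factory=dict)
    omega: dict = field(default_factory=dict)
    mh: MHSettings = field(default_factory=MHSettings)
    mipd: MipdSettings = field(default_factory=MipdSettings)
    cost: CostSettings = field(default_factory=CostSettings)
    tolerance_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.mipd.n_clones < 1:
            raise InvalidInputError("n_clones must be >= 1")
        if not (0.0 < self.mipd.prob_rule <= 100.0):
            raise InvalidInputError("prob_rule must be in (0, 100]")
        unknown = set(self.population) - (_PK_KEYS | _PD_KEYS | _POP_KEYS)
        if unknown:
            raise InvalidInputError(f"unknown population override keys: {sorted(unknown)}")

    def to_population(self) -> PopulationModel:
        """default_population() with this config's overrides applied."""
        pop = default_population()
        pk_over = {k: v for k, v in self.population.items() if k in _PK_KEYS}
        pd_over = {k: v for k, v in self.population.items() if k in _PD_KEYS}
        top_over = {k: v for k, v in self.population.items() if k in _POP_KEYS}
        if pk_over:
            pop = replace(pop, pk_typical=replace(pop.pk_typical, **pk_over))
        if pd_over:
            pop = replace(pop, pd_typical=replace(pop.pd_typical, **pd_over))
        if top_over:
            pop = replace(pop, **top_over)
        if self.omega:
            om = dict(pop.omega)
            om.update(self.omega)
            pop = replace(pop, omega=om)
        return pop

    def as_dict(self) -> dict:
        d = asdict(self)
        d["mipd"]["cycles"] = list(d["mipd"]["cycles"])
        return d


def load_config(path) -> RunConfig:
    """Load a YAML/JSON config file into a RunConfig."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config root must be a mapping, got {type(raw).__name__}")
    kwargs = {}
    for key in ("population", "omega", "tolerance_ids"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    for key, cls in (("mh", MHSettings), ("mipd", MipdSettings), ("cost", CostSettings)):
        if key in raw:
            block = raw.pop(key)
            if "cycles" in block:
                block["cycles"] = tuple(block["cycles"])
            kwargs[key] = cls(**block)
    if raw:
        raise InvalidInputError(f"unknown config sections: {sorted(raw)}")
    return RunConfig(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 digest of the canonicalised configuration."""
    payload = json.dumps(cfg.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
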