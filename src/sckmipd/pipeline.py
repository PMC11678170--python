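"""Cohort-level orchestration of the MIPD workflow.

Chains conditional sampling and the per-patient decision layer over a
list of observation sets, and aggregates the recommendation summary,
probability tables, regimen-transition counts and pooled
exposure-response pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import InvalidInputError
from .estimation import sample_conditional
from .mipd import Regimen, exposure_response_window, recommend_patient

__all__ = ["PatientResult", "CohortResult", "run_mipd"]


@dataclass
class PatientResult:
    patient_id: str
    current: Regimen
    table: object
    recommendation: object
    acceptance_rate: float


@dataclass
class CohortResult:
    patients: list

    def recommendations_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            r = p.recommendation
            rows.append(
                {
                    "id": p.patient_id,
                    "current": p.current.label,
                    "selected": r.selected.label if r.selected else "",
                    "classification": r.classification,
                    "p_cycle20": r.probability if r.probability is not None else np.nan,
                    "mh_acceptance": p.acceptance_rate,
                }
            )
        return pd.DataFrame(rows)

    def tables_frame(self) -> pd.DataFrame:
        return pd.concat([p.table.to_frame() for p in self.patients], ignore_index=True)

    def classification_fractions(self) -> dict:
        n = len(self.patients)
        counts = Counter(p.recommendation.classification for p in self.patients)
        return {k: counts.get(k, 0) / n for k in ("optimized", "intensified", "maintained", "no_target")}

    def transition_edges(self) -> pd.DataFrame:
        """Current -> selected regimen transition counts (Sankey edge list)."""
        edges = Counter()
        for p in self.patients:
            sel = p.recommendation.selected
            edges[(p.current.label, sel.label if sel else "no_target")] += 1
        return pd.DataFrame(
            [{"source": s, "target": t, "count": c} for (s, t), c in sorted(edges.items())]
        )


def run_mipd(
    obs_sets,
    currents,
    pop,
    config: RunConfig | None = None,
    seed=None,
    collect_pairs: bool = True,
):
    """Run the full MIPD procedure over a cohort.

    obs_sets: list of ObservationSet; currents: matching list of current
    Regimen.  Returns (CohortResult, pooled (trough, PASI) pair array).
    Per-patient sampler seeds are derived from `seed` via a SeedSequence
    so the run is reproducible end to end.
    """
    if len(obs_sets) != len(currents):
        raise InvalidInputError("obs_sets and currents must have equal length")
    config = config or RunConfig()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = root.spawn(len(obs_sets))
    results = []
    pairs = []
    for obs, current, ss in zip(obs_sets, currents, seeds):
        clones = sample_conditional(
            obs,
            pop,
            n_clones=config.mipd.n_clones,
            seed=np.random.default_rng(ss),
            n_burn=config.mh.n_burn,
            n_keep=config.mh.n_keep,
        )
        table, rec, outcomes = recommend_patient(
            clones,
            current,
            patient_id=obs.patient_id,
            prob_rule=config.mipd.prob_rule,
            target=config.mipd.target,
        )
        if collect_pairs:
            for out in outcomes:
                pairs.append(np.column_stack([out.ctrough_c20, out.pasi_c20]))
        results.append(
            PatientResult(
                patient_id=obs.patient_id,
                current=current,
                table=table,
                recommendation=rec,
                acceptance_rate=clones.acceptance_rate,
            )
        )
    pooled = np.vstack(pairs) if pairs else np.empty((0, 2))
    return CohortResult(results), pooled
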