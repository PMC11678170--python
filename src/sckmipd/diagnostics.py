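"""Simulation-based model diagnostics (prediction-corrected VPC).

The pcVPC follows the Bergstrand prediction-correction convention: each
observation (and each simulated replicate value) is multiplied by the
ratio of the bin's median population prediction to the subject's own
population prediction, removing the variability explained by covariates
and dosing differences before percentiles are compared.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .model import scale_pk_allometric, simulate
from .population import individual_from_etas, sample_individual, apply_residual

__all__ = ["pcvpc"]


def _time_after_dose(t, dose_times):
    prior = dose_times[dose_times <= t]
    return t - (prior.max() if prior.size else 0.0)


def _typical_predictions(obs, pop, kind):
    """Population prediction (zero random effects) at the obs times."""
    psi = individual_from_etas(pop, obs.weight, obs.pasi_obs0, {}, obs.tolerance_active)
    recs = [r for r in obs.records if r.kind == kind]
    times = np.unique([r.time for r in recs])
    traj = simulate(psi, obs.doses, times)
    series = traj.conc if kind == "pk" else traj.pasi
    lut = dict(zip(times, series))
    return recs, np.array([lut[r.time] for r in recs])


def pcvpc(datasets, pop, n_sim: int = 500, bins: int = 6, seed=None, kind: str = "pasi"):
    """Prediction-corrected visual predictive check table.

    Returns a DataFrame with, per time-after-dose bin: the bin edges and
    observation count, the prediction-corrected observed 5/50/95th
    percentiles, and the 2.5-97.5% simulation interval of each of those
    percentiles across n_sim population replicates.  Censored records are
    excluded.  Bins with fewer than 3 observations are merged into their
    left neighbour (with a warning).
    """
    if not datasets:
        raise InvalidInputError("pcvpc needs at least one observation set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    obs_tad, obs_dv, obs_pred, owners = [], [], [], []
    per_patient = []
    for obs in datasets:
        recs, preds = _typical_predictions(obs, pop, kind)
        dose_t = np.array([d.time for d in obs.doses])
        keep_recs, keep_preds = [], []
        for r, p in zip(recs, preds):
            if r.censored:
                continue
            obs_tad.append(_time_after_dose(r.time, dose_t))
            obs_dv.append(r.value)
            obs_pred.append(p)
            owners.append(len(per_patient))
            keep_recs.append(r)
            keep_preds.append(p)
        per_patient.append((obs, keep_recs, np.array(keep_preds)))
    obs_tad = np.array(obs_tad)
    obs_dv = np.array(obs_dv)
    obs_pred = np.array(obs_pred)
    if obs_dv.size == 0:
        raise InvalidInputError(f"no uncensored {kind!r} observations")

    # quantile bins on time after most recent dose
    qs = np.linspace(0, 1, bins + 1)
    edges = np.unique(np.quantile(obs_tad, qs))
    if edges.size < 2:
        edges = np.array([obs_tad.min(), obs_tad.max() + 1e-9])
    idx = np.clip(np.searchsorted(edges, obs_tad, side="right") - 1, 0, edges.size - 2)
    # merge small bins leftwards
    while edges.size > 2:
        counts = np.bincount(idx, minlength=edges.size - 1)
        small = np.where(counts < 3)[0]
        if small.size == 0:
            break
        j = small[0]
        warnings.warn(f"pcVPC bin {j} has {counts[j]} observations; merging", stacklevel=2)
        edges = np.delete(edges, max(j, 1))
        idx = np.clip(np.searchsorted(edges, obs_tad, side="right") - 1, 0, edges.size - 2)
    n_bins = edges.size - 1

    def corrected(dv, pred, idx_arr):
        out = np.empty_like(dv)
        for b in range(n_bins):
            m = idx_arr == b
            if not m.any():
                continue
            med = np.median(obs_pred[idx == b]) if (idx == b).any() else 1.0
            p = np.maximum(pred[m], 1e-12)
            out[m] = dv[m] * med / p
        return out

    pc_obs = corrected(obs_dv, obs_pred, idx)
    pcts = (5, 50, 95)
    obs_pct = {p: [np.percentile(pc_obs[idx == b], p) for b in range(n_bins)] for p in pcts}

    spec = pop.obs_spec
    sigma = pop.sigma_pk if kind == "pk" else pop.sigma_pasi
    sim_pct = {p: np.full((n_sim, n_bins), np.nan) for p in pcts}
    for s in range(n_sim):
        sim_dv, sim_pred, sim_idx = [], [], []
        ptr = 0
        for obs, recs, preds in per_patient:
            if not recs:
                continue
            psi = sample_individual(
                pop, obs.weight, obs.pasi_obs0, seed=rng, tolerance_active=obs.tolerance_active
            )
            times = np.unique([r.time for r in recs])
            traj = simulate(psi, obs.doses, times)
            series = traj.conc if kind == "pk" else traj.pasi
            lut = dict(zip(times, series))
            for k, (r, p) in enumerate(zip(recs, preds)):
                val, cens = apply_residual(lut[r.time], spec, kind, sigma, rng)
                if cens:
                    continue
                sim_dv.append(val)
                sim_pred.append(p)
                sim_idx.append(idx[ptr + k])
            ptr += len(recs)
        if not sim_dv:
            continue
        sim_dv = np.array(sim_dv)
        sim_pred = np.array(sim_pred)
        sim_idx = np.array(sim_idx)
        pc_sim = corrected(sim_dv, sim_pred, sim_idx)
        for p in pcts:
            for b in range(n_bins):
                m = sim_idx == b
                if m.any():
                    sim_pct[p][s, b] = np.percentile(pc_sim[m], p)

    rows = []
    for b in range(n_bins):
        row = {
            "bin": b,
            "t_lo": edges[b],
            "t_hi": edges[b + 1],
            "n_obs": int((idx == b).sum()),
        }
        for p in pcts:
            row[f"obs_p{p}"] = obs_pct[p][b]
            band = sim_pct[p][:, b]
            band = band[np.isfinite(band)]
            row[f"sim_p{p}_lo"] = np.percentile(band, 2.5) if band.size else np.nan
            row[f"sim_p{p}_hi"] = np.percentile(band, 97.5) if band.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
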