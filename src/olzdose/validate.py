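"""Model validation: nonparametric bootstrap, visual predictive check,
and goodness-of-fit tables.

The bootstrap resamples subjects with replacement, refits each replicate
(original estimates as the starting point), and summarizes each free
parameter by its replicate median, 2.5th–97.5th percentile interval and
relative bias, bias% = (median − estimate)/estimate × 100.

The VPC simulates replicate datasets under the full model (clearance
variability + combined residual error) on the observed design, and
compares observed concentration percentiles per time-after-dose bin with
the simulation confidence band of each percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TDMDataset, build_design
from .estimation import FitResult, _get_param, _posterior_modes, _ss_conc, _typical_cl_obs, fit
from .pkmodel import PopulationModel

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "bias_percent",
    "bootstrap",
    "vpc",
    "gof",
]

log = logging.getLogger(__name__)


def bias_percent(median: float, estimate: float) -> float:
    """Relative bootstrap bias in percent: (median − estimate)/estimate × 100."""
    if estimate == 0:
        raise ValueError("estimate must be nonzero")
    return (median - estimate) / estimate * 100.0


@dataclass
class BootstrapResult:
    summary: pd.DataFrame  # index: parameter; median, ci_lo, ci_hi, bias_pct
    n_replicates: int
    n_failed: int
    unreliable: bool
    replicates: pd.DataFrame  # converged replicate estimates, one row each


@dataclass
class VPCResult:
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    percentiles: tuple
    observed: pd.DataFrame    # rows: percentile, cols: bin
    sim_median: pd.DataFrame  # median across simulations of each percentile
    sim_lo: pd.DataFrame      # lower simulation CI of each percentile
    sim_hi: pd.DataFrame
    n_simulations: int


def bootstrap(dataset: TDMDataset, fit_result: FitResult, n_replicates: int = 1000,
              seed: int = 0, n_nodes: int = 31) -> BootstrapResult:
    """Subject-resampling bootstrap of the final model.

    Each replicate dataset preserves the cohort size; refits start from
    the original estimates; non-converged replicates are dropped and
    counted, and the result is flagged unreliable above 50% failures.
    Fully reproducible given ``seed``.
    """
    if not fit_result.converged:
        raise ValueError("bootstrap requires a converged fit")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    names = fit_result.free_names
    rows = []
    n_failed = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        ds = dataset.resample_subjects(rng)
        try:
            r = fit(ds, fit_result.model, fixed_mask=fit_result.fixed_mask,
                    n_nodes=n_nodes, max_restarts=2, seed=rep)
        except Exception as exc:
            log.warning("bootstrap replicate %d failed: %s", rep, exc)
            n_failed += 1
            continue
        if not r.converged:
            n_failed += 1
            continue
        rows.append({n: _get_param(r.model, n) for n in names})
    reps = pd.DataFrame(rows, columns=list(names))
    summary = pd.DataFrame(index=list(names),
                           columns=["median", "ci_lo", "ci_hi", "bias_pct"],
                           dtype=float)
    if len(reps):
        for n in names:
            est = _get_param(fit_result.model, n)
            med = float(reps[n].median())
            summary.loc[n] = [
                med,
                float(np.percentile(reps[n], 2.5)),
                float(np.percentile(reps[n], 97.5)),
                bias_percent(med, est),
            ]
    return BootstrapResult(
        summary=summary,
        n_replicates=n_replicates,
        n_failed=n_failed,
        unreliable=n_failed > 0.5 * n_replicates,
        replicates=reps,
    )


def _simulate_dv(design, model: PopulationModel, rng, truncate_at_zero=False):
    """One replicate of observed concentrations on the observed design."""
    eta = rng.normal(0.0, model.omega_cl, size=design.n_subjects)
    tvcl = _typical_cl_obs(design, model)
    v = model.v_typical * (design.wt / model.ref_weight) ** model.allo_v
    cl = tvcl * np.exp(eta[design.sub_idx])
    pred = _ss_conc(design.t_after, design.amt, design.tau, cl, v, model.ka)
    dv = (pred * (1.0 + rng.normal(0.0, model.sigma_prop, size=design.n_obs))
          + rng.normal(0.0, model.sigma_add, size=design.n_obs))
    if truncate_at_zero:
        dv = np.maximum(dv, 0.0)
    return dv


def vpc(dataset: TDMDataset, model: PopulationModel, n_simulations: int = 500,
        percentiles=(5.0, 50.0, 95.0), n_bins: int = 8, seed: int = 0,
        ci: float = 95.0, truncate_at_zero: bool = False) -> VPCResult:
    """Visual predictive check on the observed design.

    Bins observations by time after dose (quantile-based edges, at most
    ``n_bins`` non-empty bins), and contrasts observed percentiles with
    the ``ci``% simulation interval of each percentile under the model.
    """
    if n_simulations < 100:
        raise ValueError("n_simulations must be >= 100")
    design = build_design(dataset, tuple(e.name for e in model.cl_covariates))
    t = design.t_after
    dv = design.dv
    edges = np.unique(np.quantile(t, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 2:
        edges = np.array([t.min() - 0.5, t.max() + 0.5])
    idx = np.clip(np.digitize(t, edges[1:-1]), 0, len(edges) - 2)

    kept = []
    for b in range(len(edges) - 1):
        if np.sum(idx == b) == 0:
            log.warning("VPC: empty time bin %d dropped", b)
        else:
            kept.append(b)
    cols = [f"bin{b}" for b in kept]
    mids = np.array([t[idx == b].mean() for b in kept])

    obs = pd.DataFrame(
        {c: np.percentile(dv[idx == b], percentiles) for c, b in zip(cols, kept)},
        index=list(percentiles),
    )
    rng = np.random.default_rng(seed)
    sims = np.empty((n_simulations, len(percentiles), len(kept)))
    for s in range(n_simulations):
        sim_dv = _simulate_dv(design, model, rng, truncate_at_zero)
        for j, b in enumerate(kept):
            sims[s, :, j] = np.percentile(sim_dv[idx == b], percentiles)
    alpha = (100.0 - ci) / 2.0
    med = pd.DataFrame(np.median(sims, axis=0), index=list(percentiles), columns=cols)
    lo = pd.DataFrame(np.percentile(sims, alpha, axis=0), index=list(percentiles), columns=cols)
    hi = pd.DataFrame(np.percentile(sims, 100 - alpha, axis=0), index=list(percentiles), columns=cols)
    return VPCResult(bin_edges=edges, bin_mid=mids, percentiles=tuple(percentiles),
                     observed=obs, sim_median=med, sim_lo=lo, sim_hi=hi,
                     n_simulations=n_simulations)


def gof(dataset: TDMDataset, fit_result: FitResult) -> pd.DataFrame:
    """Goodness-of-fit table: one row per observation.

    PRED is the population prediction (eta = 0); IPRED uses the posterior
    -mode (empirical Bayes) eta.  iWRES standardizes by the residual SD at
    IPRED; WRES standardizes the population residual by the model-implied
    marginal SD at eta = 0 (first-order clearance-variability term plus
    residual variance).
    """
    if not fit_result.converged:
        raise ValueError("GOF requires a converged fit")
    model = fit_result.model
    design = build_design(dataset, tuple(e.name for e in model.cl_covariates))
    tvcl = _typical_cl_obs(design, model)
    v = model.v_typical * (design.wt / model.ref_weight) ** model.allo_v
    pred = _ss_conc(design.t_after, design.amt, design.tau, tvcl, v, model.ka)

    if model.omega_cl > 0:
        eta_hat, _ = _posterior_modes(design, model)
    else:
        eta_hat = np.zeros(design.n_subjects)
    cl_ind = tvcl * np.exp(eta_hat[design.sub_idx])
    ipred = _ss_conc(design.t_after, design.amt, design.tau, cl_ind, v, model.ka)

    res_var_i = ipred**2 * model.sigma_prop**2 + model.sigma_add**2
    iwres = (design.dv - ipred) / np.sqrt(res_var_i)

    # first-order sensitivity of the prediction to eta for the marginal SD
    h = 1e-4
    pred_p = _ss_conc(design.t_after, design.amt, design.tau, tvcl * np.exp(h), v, model.ka)
    dpred = (pred_p - pred) / h
    marg_var = dpred**2 * model.omega_cl**2 + pred**2 * model.sigma_prop**2 + model.sigma_add**2
    wres = (design.dv - pred) / np.sqrt(marg_var)

    return pd.DataFrame(dict(
        ID=design.subject_ids[design.sub_idx],
        time=design.t_after,
        dv=design.dv,
        pred=pred,
        ipred=ipred,
        wres=wres,
        iwres=iwres,
        abs_iwres=np.abs(iwres),
    ))
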