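"""Synthetic cohorts and sparse TDM datasets.

No public accession exists for the original 39-patient therapeutic-drug-
monitoring cohort, so this module generates virtual cohorts with the same
statistical structure: body weight from a truncated normal
(70.01 ± 8.23 kg on [45, 85] kg), a Bernoulli quetiapine co-medication
flag, lognormal between-subject variability on clearance, steady-state
oral dosing, and 1–3 trough samples per subject drawn shortly before a
scheduled dose with combined proportional + additive residual error.

Dosing emulates real TDM practice: per-subject daily doses vary across
the cohort (clinicians titrate), quetiapine users sit on much lower doses
(the interaction cuts clearance ~6.6-fold), and both once- and twice-
daily regimens occur.  This heterogeneity is what makes V/F and the two
residual-error components identifiable from trough-only data; a cohort
in which everyone takes the same dose at the same interval yields
observations at a single concentration level and cannot separate them.

Two prevalence presets are provided: the default uses quetiapine
prevalence 0.3 so the interaction coefficient is identifiable in recovery
experiments; ``paper_faithful_spec`` keeps the observed 2/39.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import TDMDataset
from .pkmodel import (
    DosingRegimen,
    PopulationModel,
    Subject,
    apply_residual,
    conc_steady_state,
)

__all__ = [
    "CohortSpec",
    "paper_faithful_spec",
    "generate_cohort",
    "generate_tdm",
    "make_dataset",
    "truncated_weight_moments",
]


def _as_range(x) -> tuple[float, float]:
    if np.isscalar(x):
        return float(x), float(x)
    lo, hi = x
    if not 0 <= lo <= hi:
        raise ValueError("dose range must satisfy 0 <= lo <= hi")
    return float(lo), float(hi)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a virtual TDM cohort.

    Weights are truncated-normal; each subject's daily dose (mg/kg/day)
    is drawn uniformly from ``daily_dose_per_kg`` (a scalar pins every
    subject to one dose), quetiapine users from the separate, lower
    ``daily_dose_per_kg_quetiapine`` range.  ``frequency`` is "QD",
    "BID", or "MIXED" (each subject QD or BID with equal probability).
    Trough samples (``obs_per_subject`` of them) are drawn up to
    ``trough_jitter`` hours before a scheduled dose.
    """

    n_subjects: int = 39
    weight_mean: float = 70.01
    weight_sd: float = 8.23
    weight_bounds: tuple[float, float] = (45.0, 85.0)
    quetiapine_prevalence: float = 0.3
    daily_dose_per_kg: float | tuple[float, float] = (0.2, 1.0)
    daily_dose_per_kg_quetiapine: float | tuple[float, float] = (0.03, 0.15)
    frequency: str = "MIXED"
    obs_per_subject: tuple[int, int] = (1, 3)
    trough_jitter: float = 1.0
    truncate_dv_at_zero: bool = True

    def __post_init__(self):
        lo, hi = self.weight_bounds
        if not lo < hi:
            raise ValueError("weight bounds must be ordered")
        if not 0.0 <= self.quetiapine_prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.frequency not in ("QD", "BID", "MIXED"):
            raise ValueError("frequency must be 'QD', 'BID' or 'MIXED'")
        _as_range(self.daily_dose_per_kg)
        _as_range(self.daily_dose_per_kg_quetiapine)
        lo, hi = self.obs_per_subject
        if not 1 <= lo <= hi:
            raise ValueError("obs_per_subject must satisfy 1 <= lo <= hi")


def paper_faithful_spec(**overrides) -> CohortSpec:
    """The cohort as reported: n=39 with quetiapine prevalence 2/39."""
    kw: dict = dict(n_subjects=39, quetiapine_prevalence=2.0 / 39.0)
    kw.update(overrides)
    return CohortSpec(**kw)


def generate_cohort(spec: CohortSpec, model: PopulationModel,
                    rng: np.random.Generator) -> list[Subject]:
    """Draw subjects: truncated-normal weight, Bernoulli quetiapine flag,
    and a realized random effect eta_CL ~ N(0, omega²) from ``model``."""
    lo, hi = spec.weight_bounds
    a = (lo - spec.weight_mean) / spec.weight_sd
    b = (hi - spec.weight_mean) / spec.weight_sd
    weights = stats.truncnorm.rvs(
        a, b, loc=spec.weight_mean, scale=spec.weight_sd,
        size=spec.n_subjects, random_state=rng,
    )
    que = (rng.random(spec.n_subjects) < spec.quetiapine_prevalence).astype(int)
    etas = rng.normal(0.0, model.omega_cl, size=spec.n_subjects)
    return [
        Subject(subject_id=i + 1, weight=float(w), quetiapine=int(q), eta_cl=float(e))
        for i, (w, q, e) in enumerate(zip(weights, que, etas))
    ]


def truncated_weight_moments(spec: CohortSpec) -> tuple[float, float]:
    """Exact mean and SD of the truncated-normal weight distribution."""
    lo, hi = spec.weight_bounds
    a = (lo - spec.weight_mean) / spec.weight_sd
    b = (hi - spec.weight_mean) / spec.weight_sd
    dist = stats.truncnorm(a, b, loc=spec.weight_mean, scale=spec.weight_sd)
    return float(dist.mean()), float(dist.std())


def generate_tdm(cohort: list[Subject], model: PopulationModel,
                 spec: CohortSpec, rng: np.random.Generator) -> TDMDataset:
    """Simulate a sparse steady-state trough TDM dataset for ``cohort``.

    Each subject gets one steady-state dose row (SS=1 with interval II)
    and 1–3 observation rows at successive scheduled troughs, with
    residual error applied; observed DVs are truncated at zero by
    default.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rows = []
    for s in cohort:
        rng_rng = _as_range(
            spec.daily_dose_per_kg_quetiapine if s.quetiapine else spec.daily_dose_per_kg
        )
        per_kg = rng.uniform(*rng_rng) if rng_rng[0] < rng_rng[1] else rng_rng[0]
        if spec.frequency == "MIXED":
            tau = 12.0 if rng.random() < 0.5 else 24.0
        else:
            tau = 24.0 if spec.frequency == "QD" else 12.0
        daily = per_kg * s.weight
        amt = daily * tau / 24.0
        cl = (
            model.cl_typical
            * (s.weight / model.ref_weight) ** model.allo_cl
            * (1.0 + model.theta_que * s.quetiapine)
            * np.exp(s.eta_cl)
        )
        v = model.v_typical * (s.weight / model.ref_weight) ** model.allo_v
        regimen = DosingRegimen(dose_amount=amt, interval=tau)
        rows.append(dict(ID=s.subject_id, TIME=0.0, AMT=amt, EVID=1, MDV=1,
                         DV=np.nan, WT=s.weight, QUE=s.quetiapine, SS=1, II=tau))
        lo, hi = spec.obs_per_subject
        n_obs = int(rng.integers(lo, hi + 1))
        for k in range(n_obs):
            jitter = rng.uniform(0.0, spec.trough_jitter)
            t_after = tau - jitter
            time = k * tau + t_after
            pred = conc_steady_state(t_after, regimen, cl, v, model.ka)
            eps_p = rng.normal(0.0, model.sigma_prop)
            eps_a = rng.normal(0.0, model.sigma_add)
            dv = apply_residual(pred, eps_p, eps_a)
            if spec.truncate_dv_at_zero:
                dv = max(dv, 0.0)
            rows.append(dict(ID=s.subject_id, TIME=time, AMT=0.0, EVID=0, MDV=0,
                             DV=dv, WT=s.weight, QUE=s.quetiapine, SS=0, II=0.0))
    df = pd.DataFrame(rows).sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
    return TDMDataset(df)


def make_dataset(spec: CohortSpec, model: PopulationModel, seed: int,
                 extra_noise_covariates: int = 0) -> TDMDataset:
    """Convenience: cohort + TDM in one seeded call.

    ``extra_noise_covariates`` appends that many subject-level binary
    columns (NOISE1, NOISE2, ...) unrelated to the PK, for stepwise
    type-I-error experiments.
    """
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(spec, model, rng)
    ds = generate_tdm(cohort, model, spec, rng)
    if extra_noise_covariates:
        df = ds.df
        for j in range(1, extra_noise_covariates + 1):
            flags = {s.subject_id: int(rng.random() < 0.5) for s in cohort}
            df[f"NOISE{j}"] = df["ID"].map(flags)
        ds = TDMDataset(df)
    return ds
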