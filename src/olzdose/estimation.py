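"""Maximum marginal likelihood estimation from sparse trough data.

The model has a single lognormal random effect (on clearance), so the
per-subject marginal likelihood is a 1-D integral over eta,

    L_i = ∫ Π_j N(dv_ij ; f_ij(eta), f_ij(eta)² σ_p² + σ_a²) φ(eta; 0, ω²) deta,

which is evaluated *exactly* (to quadrature precision) by adaptive
Gauss–Hermite quadrature: the integrand is re-centered at its mode with a
Laplace width before applying the Hermite rule.  This sidesteps the FOC
approximations of classical NLME software; the objective (OFV) is
−2 Σ_i log L_i including all 2π constants, so only OFV *differences* are
comparable with software that drops them.

Free parameters are estimated on transformed scales (log for positive
parameters, log(1+θ) for the bounded linear covariate coefficients) with
a Nelder–Mead search and seeded restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data import ObsDesign, TDMDataset, build_design
from .pkmodel import CovariateEffect, PopulationModel

__all__ = [
    "FitResult",
    "CovariateCandidate",
    "neg2_loglik",
    "fit",
    "rse_estimates",
    "eta_shrinkage",
    "stepwise_select",
    "StepRecord",
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
]

log = logging.getLogger(__name__)

# stepwise OFV thresholds: inclusion drop > 6.63 (chi2_1, p<0.01),
# exclusion rise > 10.8 (p<0.001)
FORWARD_THRESHOLD = 6.63
BACKWARD_THRESHOLD = 10.8

_LOG2PI = float(np.log(2.0 * np.pi))
_DEFAULT_NODES = 31
_KA_KE_GUARD = 1e-6


@dataclass
class FitResult:
    model: PopulationModel
    ofv: float
    converged: bool
    n_subjects: int
    n_obs: int
    free_names: tuple[str, ...]
    fixed_mask: frozenset
    rse: dict = field(default_factory=dict)
    n_evals: int = 0
    message: str = ""


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate–parameter relation to try during stepwise selection."""

    parameter_target: str  # only "cl" is supported
    covariate_name: str
    form: str  # "power" | "linear"
    centering_value: float | None = None

    def __post_init__(self):
        if self.form not in ("power", "linear"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.parameter_target != "cl":
            raise ValueError("only clearance covariates are supported")


@dataclass(frozen=True)
class StepRecord:
    phase: str  # "forward" | "backward"
    candidate: str
    delta_ofv: float
    action: str  # "included" | "excluded" | "kept" | "rejected" | "skipped"


# ---------------------------------------------------------------------------
# vectorized steady-state predictions over heterogeneous designs
# ---------------------------------------------------------------------------

def _ss_conc(t, amt, tau, cl, v, ka):
    """Steady-state concentration, broadcasting over arrays (ng/mL)."""
    ke = cl / v
    dose_ug = amt * 1000.0
    close = np.abs(ka - ke) <= _KA_KE_GUARD * ke
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        acc_ke = np.exp(-ke * t) / (1.0 - np.exp(-ke * tau))
        acc_ka = np.exp(-ka * t) / (1.0 - np.exp(-ka * tau))
        denom = np.where(close, 1.0, ka - ke)
        general = (dose_ug * ka / (v * denom)) * (acc_ke - acc_ka)
        ek = np.exp(-ke * tau)
        limit = (dose_ug * ke / v) * acc_ke * (t + tau * ek / (1.0 - ek))
    return np.maximum(np.where(close, limit, general), 0.0)


def _typical_cl_obs(design: ObsDesign, model: PopulationModel):
    cl = (
        model.cl_typical
        * (design.wt / model.ref_weight) ** model.allo_cl
        * (1.0 + model.theta_que * design.que)
    )
    for eff in model.cl_covariates:
        cl = cl * eff.multiplier(design.extras[eff.name])
    return cl


def _log_joint(design: ObsDesign, model: PopulationModel, eta):
    """Per-subject log of (likelihood of its observations × eta prior).

    ``eta`` has shape (n_subjects,) or (n_subjects, K); returns matching
    (n_subjects,) or (n_subjects, K).
    """
    # clip to keep exp(eta) finite; |eta| = 30 is ~163 SD at omega 0.184
    eta = np.clip(np.asarray(eta, dtype=float), -30.0, 30.0)
    eta_obs = eta[design.sub_idx]  # (n_obs,) or (n_obs, K)
    tvcl = _typical_cl_obs(design, model)
    v = model.v_typical * (design.wt / model.ref_weight) ** model.allo_v
    if eta.ndim == 2:
        tvcl, v = tvcl[:, None], v[:, None]
        t, amt, tau = design.t_after[:, None], design.amt[:, None], design.tau[:, None]
        dv = design.dv[:, None]
    else:
        t, amt, tau, dv = design.t_after, design.amt, design.tau, design.dv
    cl = tvcl * np.exp(eta_obs)
    pred = _ss_conc(t, amt, tau, cl, v, model.ka)
    var = pred**2 * model.sigma_prop**2 + model.sigma_add**2
    if np.any(var <= 0):
        bad = np.nonzero(~(var > 0))[0]
        sid = design.subject_ids[design.sub_idx[int(bad.flat[0])]]
        raise ValueError(f"non-positive residual variance for subject {sid}")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ll_obs = -0.5 * (_LOG2PI + np.log(var) + (dv - pred) ** 2 / var)
    ll_obs = np.where(np.isfinite(ll_obs), ll_obs, -1e30)
    shape = (design.n_subjects,) + eta.shape[1:]
    per_sub = np.zeros(shape)
    np.add.at(per_sub, design.sub_idx, ll_obs)
    if model.omega_cl > 0:
        per_sub += -0.5 * (
            _LOG2PI + 2.0 * np.log(model.omega_cl) + eta**2 / model.omega_cl**2
        )
    if not np.all(np.isfinite(per_sub)):
        bad = int(np.nonzero(~np.isfinite(per_sub))[0][0])
        raise ValueError(
            f"non-finite likelihood contribution for subject {design.subject_ids[bad]}"
        )
    return per_sub


def _posterior_modes(design: ObsDesign, model: PopulationModel, eta0=None):
    """Vectorized Newton search for the per-subject mode of the log joint.

    Returns (mode, curvature d²g/deta²) arrays of shape (n_subjects,).
    """
    n = design.n_subjects
    if eta0 is None:
        # coarse global scan guards against far-out or multimodal posteriors
        span = max(6.0 * model.omega_cl, 3.0)
        grid = np.linspace(-span, span, 25)
        G = _log_joint(design, model, np.tile(grid, (n, 1)))
        eta = grid[np.argmax(G, axis=1)]
    else:
        eta = np.array(eta0, dtype=float)
    h = 1e-4
    g0 = _log_joint(design, model, eta)
    for _ in range(50):
        gp = _log_joint(design, model, eta + h)
        gm = _log_joint(design, model, eta - h)
        d1 = (gp - gm) / (2 * h)
        d2 = (gp - 2 * g0 + gm) / h**2
        step = np.where(d2 < 0, -d1 / np.where(d2 < 0, d2, -1.0), np.sign(d1) * 0.5)
        step = np.clip(step, -1.0, 1.0)
        # backtracking keeps the ascent monotone (guaranteed convergence)
        new = np.clip(eta + step, -29.0, 29.0)
        gn = _log_joint(design, model, new)
        for _ in range(10):
            worse = gn < g0 - 1e-12
            if not np.any(worse):
                break
            step = np.where(worse, 0.5 * step, step)
            cand = np.clip(eta + step, -29.0, 29.0)
            gc = _log_joint(design, model, cand)
            new = np.where(worse, cand, new)
            gn = np.where(worse, gc, gn)
        moved = np.max(np.abs(new - eta))
        eta, g0 = new, gn
        if moved < 1e-7:
            break
    gp = _log_joint(design, model, eta + h)
    gm = _log_joint(design, model, eta - h)
    d2 = (gp - 2 * g0 + gm) / h**2
    return eta, d2


def _marginal_neg2ll(design: ObsDesign, model: PopulationModel,
                     n_nodes: int = _DEFAULT_NODES, eta_warm=None):
    """−2 log marginal likelihood by adaptive Gauss–Hermite quadrature."""
    if design.n_obs == 0:
        raise ValueError("dataset contains no usable observations")
    if model.omega_cl == 0.0:
        ll = _log_joint(design, model, np.zeros(design.n_subjects))
        return -2.0 * float(np.sum(ll)), np.zeros(design.n_subjects)
    mode, d2 = _posterior_modes(design, model, eta_warm)
    sd = np.where(d2 < 0, np.sqrt(-1.0 / np.where(d2 < 0, d2, -1.0)), model.omega_cl)
    x, w = hermgauss(n_nodes)
    nodes = mode[:, None] + np.sqrt(2.0) * sd[:, None] * x[None, :]
    g = _log_joint(design, model, nodes)
    log_l = (
        0.5 * np.log(2.0) + np.log(sd)
        + logsumexp(np.log(w)[None, :] + x[None, :] ** 2 + g, axis=1)
    )
    return -2.0 * float(np.sum(log_l)), mode


def neg2_loglik(dataset: TDMDataset, model: PopulationModel,
                n_nodes: int = _DEFAULT_NODES) -> float:
    """Objective function value: −2 × log marginal likelihood (with 2π
    constants), the quantity whose nested differences follow χ²."""
    design = build_design(dataset, tuple(e.name for e in model.cl_covariates))
    ofv, _ = _marginal_neg2ll(design, model, n_nodes)
    return ofv


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

_BASE_FREE = ("cl_typical", "v_typical", "theta_que", "omega_cl", "sigma_prop", "sigma_add")
_LOG_PARAMS = {"cl_typical", "v_typical", "omega_cl", "sigma_prop", "sigma_add"}
_FLOOR = 1e-8


def _free_names(model: PopulationModel, fixed_mask) -> tuple[str, ...]:
    names = [n for n in _BASE_FREE if n not in fixed_mask]
    names += [f"beta:{e.name}" for e in model.cl_covariates
              if f"beta:{e.name}" not in fixed_mask]
    return tuple(names)


def _get_param(model: PopulationModel, name: str) -> float:
    if name.startswith("beta:"):
        key = name[5:]
        for e in model.cl_covariates:
            if e.name == key:
                return e.theta
        raise KeyError(name)
    return getattr(model, name)


def _set_params(model: PopulationModel, names, values) -> PopulationModel:
    kw = {}
    effects = list(model.cl_covariates)
    for name, val in zip(names, values):
        if name.startswith("beta:"):
            key = name[5:]
            for i, e in enumerate(effects):
                if e.name == key:
                    effects[i] = CovariateEffect(e.name, e.form, float(val), e.centering)
                    break
            else:
                raise KeyError(name)
        else:
            kw[name] = float(val)
    return model.with_(cl_covariates=tuple(effects), **kw)


def _effect_form(model: PopulationModel, name: str) -> str:
    key = name[5:]
    for e in model.cl_covariates:
        if e.name == key:
            return e.form
    raise KeyError(name)


def _to_transformed(model, names):
    out = []
    for n in names:
        v = _get_param(model, n)
        if n in _LOG_PARAMS:
            out.append(np.log(max(v, _FLOOR)))
        elif n == "theta_que" or (n.startswith("beta:") and _effect_form(model, n) == "linear"):
            out.append(np.log1p(v))  # requires 1 + theta > 0
        else:
            out.append(v)
    return np.asarray(out)


def _from_transformed(model, names, z):
    vals = []
    for n, t in zip(names, z):
        if n in _LOG_PARAMS:
            vals.append(np.exp(t))
        elif n == "theta_que" or (n.startswith("beta:") and _effect_form(model, n) == "linear"):
            vals.append(np.expm1(t))
        else:
            vals.append(t)
    return _set_params(model, names, vals)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(dataset: TDMDataset, initial: PopulationModel, fixed_mask=(),
        n_nodes: int = _DEFAULT_NODES, max_restarts: int = 3,
        seed: int = 0, compute_rse: bool = False) -> FitResult:
    """Minimize the OFV over the free parameters.

    Ka, the allometric exponents and the reference weight are always held
    fixed; ``fixed_mask`` names further parameters to hold at their
    ``initial`` values (e.g. ``{"theta_que"}`` for the no-covariate base
    model).  Non-convergence after seeded restarts returns the best point
    found with ``converged=False``.
    """
    fixed_mask = frozenset(fixed_mask)
    names = _free_names(initial, fixed_mask)
    design = build_design(dataset, tuple(e.name for e in initial.cl_covariates))
    if design.n_obs < len(names):
        raise ValueError(
            f"{design.n_obs} observations cannot identify {len(names)} free parameters"
        )

    state = {"eta": None, "evals": 0}
    z_ref = _to_transformed(initial, names)

    def objective(z):
        state["evals"] += 1
        try:
            m = _from_transformed(initial, names, z)
        except ValueError:
            return 1e12
        try:
            ofv, mode = _marginal_neg2ll(design, m, n_nodes, state["eta"])
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(ofv):
            return 1e12
        state["eta"] = mode
        # soft box +-4 natural-log units around the start keeps the search
        # off unidentifiable ridges (e.g. V -> inf at trough-only designs)
        excess = np.maximum(np.abs(z - z_ref) - 4.0, 0.0)
        return ofv + 1e4 * float(np.sum(excess**2))

    rng = np.random.default_rng(seed)
    z0 = _to_transformed(initial, names)
    best = None
    converged = False
    message = ""
    for attempt in range(max_restarts):
        # fatol is scaled to ~1e-6 relative on the OFV magnitude
        f0 = objective(z0)
        fatol = max(1e-6 * abs(f0), 1e-6)
        res = minimize(
            objective, z0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": fatol, "maxiter": 4000,
                     "maxfev": 6000, "adaptive": True},
        )
        if best is None or res.fun < best.fun:
            best = res
        message = res.message
        if res.success and np.isfinite(res.fun) and res.fun < 1e11:
            converged = True
            best = res
            break
        z0 = best.x + rng.normal(0.0, 0.1, size=len(names))
        log.warning("fit restart %d: %s", attempt + 1, res.message)

    model_hat = _from_transformed(initial, names, best.x)
    result = FitResult(
        model=model_hat,
        ofv=float(best.fun),
        converged=converged,
        n_subjects=design.n_subjects,
        n_obs=design.n_obs,
        free_names=names,
        fixed_mask=fixed_mask,
        n_evals=state["evals"],
        message=str(message),
    )
    if compute_rse and converged:
        result.rse = rse_estimates(dataset, result, n_nodes=n_nodes)
    return result


def rse_estimates(dataset: TDMDataset, fit_result: FitResult,
                  n_nodes: int = _DEFAULT_NODES) -> dict:
    """Relative standard errors (%) from the inverse numerical Hessian of
    OFV/2 at the optimum, on the natural parameter scale.  Fixed
    parameters get no entry; a non-positive-definite Hessian returns an
    empty dict flagged via the ``"_flag"`` key."""
    if not fit_result.converged:
        raise ValueError("RSEs require a converged fit")
    names = fit_result.free_names
    model = fit_result.model
    design = build_design(dataset, tuple(e.name for e in model.cl_covariates))
    theta = np.array([_get_param(model, n) for n in names])

    def f(vec):
        m = _set_params(model, names, vec)
        ofv, _ = _marginal_neg2ll(design, m, n_nodes)
        return 0.5 * ofv

    k = len(names)
    f0 = f(theta)
    # finite-difference step must beat quadrature/optimizer noise but stay
    # in the quadratic regime; walk a small ladder until the Hessian is PD
    for rel in (1e-2, 2e-2, 5e-3, 5e-2):
        steps = np.maximum(np.abs(theta) * rel, 1e-4)
        H = np.empty((k, k))
        for i in range(k):
            ei = np.zeros(k); ei[i] = steps[i]
            H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k); ej[j] = steps[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            continue
        d = np.diag(cov)
        if np.all(d > 0):
            se = np.sqrt(d)
            return {n: 100.0 * s / abs(t)
                    for n, s, t in zip(names, se, theta) if t != 0}
    return {"_flag": "non-positive-definite Hessian"}


def empirical_bayes_etas(dataset: TDMDataset, model: PopulationModel) -> np.ndarray:
    """Posterior-mode (empirical Bayes) random effect per subject."""
    design = build_design(dataset, tuple(e.name for e in model.cl_covariates))
    if model.omega_cl == 0:
        return np.zeros(design.n_subjects)
    mode, _ = _posterior_modes(design, model)
    return mode


def eta_shrinkage(dataset: TDMDataset, fit_result: FitResult) -> float:
    """η-shrinkage in percent: 100·(1 − SD(EBE η)/ω)."""
    omega = fit_result.model.omega_cl
    if omega == 0:
        raise ValueError("shrinkage undefined for omega_cl = 0")
    ebe = empirical_bayes_etas(dataset, fit_result.model)
    return 100.0 * (1.0 - float(np.std(ebe, ddof=1)) / omega)


# ---------------------------------------------------------------------------
# stepwise covariate selection
# ---------------------------------------------------------------------------

def _candidate_centering(cand: CovariateCandidate, dataset: TDMDataset) -> float:
    if cand.centering_value is not None:
        return cand.centering_value
    if cand.form == "linear":
        return 1.0
    sub = dataset.subject_table()
    return float(sub[cand.covariate_name].median())


def _model_with(base: PopulationModel, included, dataset,
                carried: dict) -> tuple[PopulationModel, frozenset]:
    """Build (model, fixed_mask) for a set of included candidates.

    The quetiapine linear-on-CL candidate occupies the model's dedicated
    ``theta_que`` slot; other candidates become generic CL covariate
    effects.  ``carried`` maps parameter name -> last estimate, used as a
    warm start."""
    fixed = {"theta_que"}
    effects = []
    model = base.with_(theta_que=0.0, cl_covariates=())
    for cand in included:
        if cand.covariate_name == "QUE" and cand.form == "linear":
            fixed.discard("theta_que")
            model = model.with_(theta_que=carried.get("theta_que", -0.3))
        else:
            name = f"beta:{cand.covariate_name}"
            theta0 = carried.get(name, 0.1 if cand.form == "power" else 0.0)
            effects.append(
                CovariateEffect(cand.covariate_name, cand.form, theta0,
                                _candidate_centering(cand, dataset))
            )
    model = model.with_(cl_covariates=tuple(effects))
    return model, frozenset(fixed)


def stepwise_select(dataset: TDMDataset, base: PopulationModel,
                    candidates: list[CovariateCandidate],
                    forward_threshold: float = FORWARD_THRESHOLD,
                    backward_threshold: float = BACKWARD_THRESHOLD,
                    n_nodes: int = _DEFAULT_NODES,
                    seed: int = 0) -> tuple[FitResult, list[StepRecord]]:
    """Forward-inclusion / backward-elimination covariate search.

    Forward: refit with each remaining candidate added; the largest OFV
    drop wins if it exceeds ``forward_threshold`` (ties broken by
    candidate order).  Backward: any included covariate whose removal
    raises the OFV by no more than ``backward_threshold`` is removed
    (smallest rise first), iterating to stability.  Returns the final fit
    and the decision trace.
    """
    trace: list[StepRecord] = []
    carried: dict[str, float] = {}

    def run(included):
        model, fixed = _model_with(base, included, dataset, carried)
        return fit(dataset, model, fixed_mask=fixed, n_nodes=n_nodes, seed=seed)

    current: list[CovariateCandidate] = []
    current_fit = run(current)
    _remember(carried, current_fit)

    remaining = list(candidates)
    while remaining:
        results = []
        for cand in remaining:
            try:
                r = run(current + [cand])
            except Exception as exc:  # fit failure: skip candidate this round
                log.warning("candidate %s skipped: %s", cand.covariate_name, exc)
                trace.append(StepRecord("forward", cand.covariate_name, np.nan, "skipped"))
                continue
            results.append((cand, r, current_fit.ofv - r.ofv))
        if not results:
            break
        best_cand, best_fit, best_drop = max(results, key=lambda t: t[2])
        if best_drop > forward_threshold:
            trace.append(StepRecord("forward", best_cand.covariate_name, best_drop, "included"))
            for cand, _, drop in results:
                if cand is not best_cand:
                    trace.append(StepRecord("forward", cand.covariate_name, drop, "rejected"))
            current.append(best_cand)
            current_fit = best_fit
            _remember(carried, current_fit)
            remaining.remove(best_cand)
        else:
            for cand, _, drop in results:
                trace.append(StepRecord("forward", cand.covariate_name, drop, "rejected"))
            break

    changed = True
    while changed and current:
        changed = False
        rises = []
        for cand in current:
            reduced = [c for c in current if c is not cand]
            try:
                r = run(reduced)
            except Exception as exc:
                log.warning("backward step for %s skipped: %s", cand.covariate_name, exc)
                trace.append(StepRecord("backward", cand.covariate_name, np.nan, "skipped"))
                continue
            rises.append((cand, r, r.ofv - current_fit.ofv))
        if not rises:
            break
        worst_cand, worst_fit, worst_rise = min(rises, key=lambda t: t[2])
        if worst_rise <= backward_threshold:
            trace.append(StepRecord("backward", worst_cand.covariate_name, worst_rise, "excluded"))
            current.remove(worst_cand)
            current_fit = worst_fit
            _remember(carried, current_fit)
            changed = True
        else:
            for cand, _, rise in rises:
                trace.append(StepRecord("backward", cand.covariate_name, rise, "kept"))
    return current_fit, trace


def _remember(carried: dict, fit_result: FitResult) -> None:
    for n in fit_result.free_names:
        carried[n] = _get_param(fit_result.model, n)
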