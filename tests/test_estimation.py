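"""Marginal likelihood, fitting, uncertainty and covariate selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import trapezoid

from olzdose import TDMDataset, default_model, eta_shrinkage, fit, neg2_loglik, rse_estimates
from olzdose.cohort import CohortSpec, make_dataset
from olzdose.data import build_design
from olzdose.estimation import CovariateCandidate, _log_joint, stepwise_select
from olzdose.pkmodel import DosingRegimen, conc_steady_state


def brute_force_ofv(dataset, model, span=6.0, n=20001):
    """Independent oracle: trapezoidal integration of the marginal
    likelihood over eta."""
    design = build_design(dataset)
    etas = np.linspace(-span * model.omega_cl, span * model.omega_cl, n)
    g = _log_joint(design, model, np.tile(etas, (design.n_subjects, 1)))
    return -2.0 * float(np.sum(np.log(trapezoid(np.exp(g), etas, axis=1))))


def single_obs_dataset(dv, amt=24.5, tau=12.0, wt=70.0):
    return TDMDataset(pd.DataFrame(dict(
        ID=[1, 1], TIME=[0.0, tau], AMT=[amt, 0.0], EVID=[1, 0], MDV=[1, 0],
        DV=[np.nan, dv], WT=[wt, wt], QUE=[0, 0], SS=[1, 0], II=[tau, 0.0],
    )))


class TestObjectiveFunction:
    def test_degenerate_single_point_gaussian(self):
        """With omega=0 and a perfect observation the OFV reduces to the
        Gaussian normalization constant log(2*pi*var)."""
        m = default_model().with_(omega_cl=0.0)
        pred = conc_steady_state(12.0, DosingRegimen(24.5, 12.0), 18.5, 106.0, 0.861)
        ds = single_obs_dataset(pred)
        var = pred**2 * m.sigma_prop**2 + m.sigma_add**2
        assert neg2_loglik(ds, m) == pytest.approx(math.log(2 * math.pi * var), rel=1e-12)

    def test_matches_brute_force_integration(self, tiny_fixture, table3_model):
        quad = neg2_loglik(tiny_fixture, table3_model)
        brute = brute_force_ofv(tiny_fixture, table3_model)
        assert quad == pytest.approx(brute, abs=1e-4)

    def test_gross_misfit_increases_ofv(self, cohort39, table3_model):
        bad = table3_model.with_(cl_typical=60.0, v_typical=30.0)
        assert neg2_loglik(cohort39, bad) > neg2_loglik(cohort39, table3_model)

    def test_invariant_to_subject_order(self, cohort39, table3_model):
        df = cohort39.df
        order = list(cohort39.subject_ids)[::-1]
        shuffled = TDMDataset(pd.concat(
            [df[df["ID"] == sid] for sid in order], ignore_index=True))
        assert neg2_loglik(shuffled, table3_model) == pytest.approx(
            neg2_loglik(cohort39, table3_model), abs=1e-8)

    def test_empty_observation_dataset_rejected(self):
        ds = single_obs_dataset(30.0)
        ds.df.loc[ds.df["EVID"] == 0, "MDV"] = 1  # flag the only obs missing
        with pytest.raises(ValueError):
            neg2_loglik(ds, default_model())


class TestFit:
    def test_noise_free_recovery(self):
        truth = default_model().with_(omega_cl=0.0, sigma_prop=1e-3, sigma_add=1e-3)
        ds = make_dataset(
            CohortSpec(n_subjects=25, obs_per_subject=(2, 3)), truth, seed=2)
        init = truth.with_(cl_typical=14.0, v_typical=80.0, theta_que=-0.6)
        r = fit(ds, init, fixed_mask={"omega_cl", "sigma_prop", "sigma_add"}, seed=0)
        assert r.converged
        assert r.model.cl_typical == pytest.approx(18.5, rel=0.02)
        assert r.model.v_typical == pytest.approx(106.0, rel=0.05)
        assert r.model.theta_que == pytest.approx(-0.848, abs=0.02)

    def test_recovery_from_half_truth_init(self):
        truth = default_model()
        ds = make_dataset(CohortSpec(n_subjects=100), truth, seed=31)
        init = truth.with_(cl_typical=9.25, v_typical=53.0, theta_que=-0.4,
                           omega_cl=0.09, sigma_prop=0.15, sigma_add=0.88)
        r = fit(ds, init, seed=0)
        assert r.converged
        assert r.model.cl_typical == pytest.approx(18.5, rel=0.2)
        assert r.model.theta_que == pytest.approx(-0.848, abs=0.1)

    def test_too_few_observations_rejected(self):
        ds = single_obs_dataset(30.0)
        with pytest.raises(ValueError, match="identify"):
            fit(ds, default_model())

    def test_nesting_monotonicity(self, cohort39, table3_model):
        """Freeing theta_que can only lower the minimized OFV (within
        optimizer tolerance)."""
        base = fit(cohort39, table3_model.with_(theta_que=0.0),
                   fixed_mask={"theta_que"}, seed=0)
        full = fit(cohort39, table3_model, seed=0)
        assert full.ofv <= base.ofv + 1e-3


class TestUncertainty:
    def test_rse_excludes_fixed_parameters(self, cohort39, fit39):
        rse = rse_estimates(cohort39, fit39)
        assert "ka" not in rse
        assert set(rse) <= set(fit39.free_names)
        assert all(v > 0 for v in rse.values())

    def test_rse_shrinks_with_sample_size(self):
        truth = default_model()
        init = truth
        rses = {}
        for n, seed in ((40, 9), (160, 9)):
            ds = make_dataset(CohortSpec(n_subjects=n), truth, seed=seed)
            r = fit(ds, init, seed=0)
            rses[n] = rse_estimates(ds, r)["cl_typical"]
        assert rses[160] < rses[40]

    def test_shrinkage_extremes(self):
        truth = default_model()
        rich = make_dataset(CohortSpec(n_subjects=30, obs_per_subject=(3, 3),
                                       daily_dose_per_kg=(0.2, 1.0)),
                            truth.with_(sigma_prop=0.05, sigma_add=0.3), seed=4)
        r_rich = fit(rich, truth.with_(sigma_prop=0.05, sigma_add=0.3),
                     fixed_mask={"sigma_prop", "sigma_add"}, seed=0)
        s_rich = eta_shrinkage(rich, r_rich)

        noisy_model = truth.with_(sigma_prop=1.5, sigma_add=10.0)
        noisy = make_dataset(CohortSpec(n_subjects=30, obs_per_subject=(1, 1)),
                             noisy_model, seed=4)
        s_noisy = eta_shrinkage(noisy, fit(noisy, noisy_model,
                                           fixed_mask={"sigma_prop", "sigma_add"},
                                           seed=0))
        assert s_rich < 25.0
        assert s_noisy > 60.0

    def test_shrinkage_undefined_without_variability(self, cohort39, fit39):
        from olzdose.estimation import FitResult
        degenerate = FitResult(model=fit39.model.with_(omega_cl=0.0), ofv=0.0,
                               converged=True, n_subjects=1, n_obs=1,
                               free_names=(), fixed_mask=frozenset())
        with pytest.raises(ValueError):
            eta_shrinkage(cohort39, degenerate)


class TestStepwise:
    def test_no_candidates_returns_base(self, cohort39, table3_model):
        final, trace = stepwise_select(cohort39, table3_model, [], seed=0)
        assert trace == []
        assert final.model.theta_que == 0.0  # base model carries no covariate

    def test_quetiapine_selected_noise_rejected(self):
        truth = default_model()
        ds = make_dataset(CohortSpec(n_subjects=60), truth, seed=42,
                          extra_noise_covariates=1)
        base = truth.with_(theta_que=0.0, cl_typical=15.0, v_typical=90.0,
                           omega_cl=0.15, sigma_prop=0.25, sigma_add=1.5)
        cands = [CovariateCandidate("cl", "QUE", "linear"),
                 CovariateCandidate("cl", "NOISE1", "linear")]
        final, trace = stepwise_select(ds, base, cands, seed=0)
        included = {r.candidate for r in trace if r.action == "included"}
        assert included == {"QUE"}
        assert final.model.theta_que == pytest.approx(-0.848, abs=0.15)
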