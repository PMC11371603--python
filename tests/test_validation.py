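"""Bootstrap, VPC and goodness-of-fit diagnostics."""

import numpy as np
import pandas as pd
import pytest

from olzdose import TDMDataset, bias_percent, bootstrap, default_model, gof, vpc
from olzdose.cohort import CohortSpec, make_dataset
from olzdose.estimation import FitResult, fit


class TestBiasFormula:
    @pytest.mark.parametrize(
        "median, estimate, expected",
        [
            (18.9, 18.5, 2.16),
            (113.0, 106.0, 6.60),
            (-0.836, -0.848, -1.42),
            (0.185, 0.184, 0.54),
            (0.271, 0.307, -11.73),
            (2.298, 1.764, 30.27),
        ],
    )
    def test_reported_bias_cells(self, median, estimate, expected):
        assert bias_percent(median, estimate) == pytest.approx(expected, abs=5e-3)

    def test_zero_estimate_rejected(self):
        with pytest.raises(ValueError):
            bias_percent(1.0, 0.0)


class TestBootstrap:
    def test_seeded_reproducibility(self, cohort39, fit39):
        a = bootstrap(cohort39, fit39, n_replicates=4, seed=21)
        b = bootstrap(cohort39, fit39, n_replicates=4, seed=21)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_cloned_cohort_gives_degenerate_intervals(self):
        m = default_model()
        one = make_dataset(CohortSpec(n_subjects=1, quetiapine_prevalence=0.0),
                           m, seed=3)
        block = one.df.copy()
        parts = []
        for i in range(12):
            b = block.copy()
            b["ID"] = i + 1
            parts.append(b)
        cloned = TDMDataset(pd.concat(parts, ignore_index=True))
        r = fit(cloned, m, fixed_mask={"theta_que", "omega_cl"}, seed=0)
        boot = bootstrap(cloned, r, n_replicates=5, seed=1)
        widths = (boot.summary["ci_hi"] - boot.summary["ci_lo"]).abs()
        scale = boot.summary["median"].abs() + 1e-9
        assert (widths / scale < 1e-3).all()

    def test_truth_inside_bootstrap_intervals(self, cohort39, fit39, table3_model):
        """Scaled-down replicate count; the generating values should sit
        inside the 95% interval for at least 3 of the 4 structural
        parameters."""
        boot = bootstrap(cohort39, fit39, n_replicates=60, seed=17)
        assert not boot.unreliable
        truths = dict(cl_typical=18.5, v_typical=106.0,
                      theta_que=-0.848, omega_cl=0.184)
        hits = sum(
            boot.summary.loc[k, "ci_lo"] <= v <= boot.summary.loc[k, "ci_hi"]
            for k, v in truths.items()
        )
        assert hits >= 3


class TestVPC:
    def test_self_consistency_coverage(self, cohort39, table3_model):
        res = vpc(cohort39, table3_model, n_simulations=300, seed=13)
        inside = 0
        total = 0
        for c in res.observed.columns:
            for p in res.percentiles:
                total += 1
                if res.sim_lo.loc[p, c] <= res.observed.loc[p, c] <= res.sim_hi.loc[p, c]:
                    inside += 1
        assert inside / total >= 0.7

    def test_gross_shift_detected(self, cohort39, table3_model):
        shifted = TDMDataset(cohort39.df.assign(
            DV=lambda d: d["DV"] + np.where(d["EVID"] == 0, 100.0, 0.0)))
        res = vpc(shifted, table3_model, n_simulations=150, seed=13)
        for c in res.observed.columns:
            assert res.observed.loc[50.0, c] > res.sim_hi.loc[50.0, c]

    def test_degenerate_model_collapses_percentiles(self):
        m = default_model().with_(omega_cl=0.0, sigma_prop=0.0, sigma_add=0.0)
        ds = make_dataset(CohortSpec(n_subjects=10, obs_per_subject=(2, 2),
                                     trough_jitter=1e-9, frequency="BID",
                                     daily_dose_per_kg=0.7,
                                     weight_mean=70.0, weight_sd=1e-9,
                                     weight_bounds=(69.99, 70.01),
                                     quetiapine_prevalence=0.0), m, seed=5)
        res = vpc(ds, m, n_simulations=100, n_bins=1, seed=1)
        col = res.observed.columns[0]
        vals = res.sim_median[col]
        assert vals.max() - vals.min() < 1e-6 * max(vals.max(), 1.0)

    def test_too_few_simulations_rejected(self, cohort39, table3_model):
        with pytest.raises(ValueError):
            vpc(cohort39, table3_model, n_simulations=50)


class TestGof:
    def test_perfect_individual_prediction_zeroes_iwres(self):
        m = default_model().with_(omega_cl=0.0, sigma_prop=0.0, sigma_add=0.0)
        ds = make_dataset(CohortSpec(n_subjects=8, quetiapine_prevalence=0.0),
                          m, seed=6)
        r = FitResult(model=m.with_(sigma_prop=0.1, sigma_add=0.5), ofv=0.0,
                      converged=True, n_subjects=8, n_obs=ds.n_obs,
                      free_names=(), fixed_mask=frozenset())
        table = gof(ds, r)
        np.testing.assert_allclose(table["iwres"], 0.0, atol=1e-8)
        np.testing.assert_allclose(table["ipred"], table["dv"], rtol=1e-8)

    def test_iwres_matches_hand_calculation(self):
        """3-point fixture with omega=0: iWRES must equal
        (dv - pred)/sqrt(pred^2 sp^2 + sa^2) computed by hand."""
        m = default_model().with_(omega_cl=0.0, sigma_prop=0.2, sigma_add=1.0)
        truth_clean = m.with_(sigma_prop=0.0, sigma_add=0.0)
        ds = make_dataset(CohortSpec(n_subjects=3, obs_per_subject=(1, 1),
                                     quetiapine_prevalence=0.0), truth_clean, seed=9)
        offsets = np.array([2.0, -3.0, 0.5])
        df = ds.df.copy()
        df.loc[df["EVID"] == 0, "DV"] = df.loc[df["EVID"] == 0, "DV"].to_numpy() + offsets
        noisy = TDMDataset(df)
        r = FitResult(model=m, ofv=0.0, converged=True, n_subjects=3, n_obs=3,
                      free_names=(), fixed_mask=frozenset())
        table = gof(noisy, r)
        pred = table["pred"].to_numpy()
        expected = offsets / np.sqrt(pred**2 * 0.04 + 1.0)
        np.testing.assert_allclose(table["iwres"], expected, atol=1e-10)

    def test_unconverged_fit_rejected(self, cohort39, table3_model):
        r = FitResult(model=table3_model, ofv=np.nan, converged=False,
                      n_subjects=39, n_obs=0, free_names=(), fixed_mask=frozenset())
        with pytest.raises(ValueError):
            gof(cohort39, r)
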