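"""Structural PK model: covariate equations, steady-state closed form,
superposition oracle, residual model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olzdose import (
    DosingRegimen,
    PopulationModel,
    Subject,
    apply_residual,
    conc_steady_state,
    conc_superposition,
    covariate_power,
    default_model,
    individual_param,
    typical_cl,
    typical_v,
)

M = default_model()


class TestCovariateModel:
    @pytest.mark.parametrize(
        "weight, que, expected",
        [
            (70.0, 0, 18.5),                      # reference individual
            (70.0, 1, 18.5 * (1 - 0.848)),        # = 2.812
            (40.0, 0, 18.5 * (40 / 70) ** 0.75),  # = 12.158...
        ],
    )
    def test_typical_clearance(self, weight, que, expected):
        assert typical_cl(weight, que, M) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "weight, expected", [(70.0, 106.0), (35.0, 53.0), (100.0, 106 * 100 / 70)]
    )
    def test_typical_volume(self, weight, expected):
        assert typical_v(weight, M) == pytest.approx(expected, rel=1e-12)

    def test_quetiapine_ratio_weight_independent(self):
        for w in np.linspace(40, 100, 61):
            ratio = typical_cl(w, 1, M) / typical_cl(w, 0, M)
            assert ratio == pytest.approx(0.152, abs=1e-12)

    def test_clearance_increasing_in_weight(self):
        w = np.linspace(40, 100, 200)
        cl = typical_cl(w, 0, M)
        assert np.all(np.diff(cl) > 0)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            typical_cl(0.0, 0, M)
        with pytest.raises(ValueError):
            typical_v(-5.0, M)

    @pytest.mark.parametrize(
        "tv, eta, expected",
        [(18.5, 0.0, 18.5), (18.5, 0.184, 18.5 * math.exp(0.184)),
         (106.0, -0.5, 106 * math.exp(-0.5))],
    )
    def test_individual_param(self, tv, eta, expected):
        assert individual_param(tv, eta) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "tv, cov, med, theta, expected",
        [(18.5, 50, 50, 0.3, 18.5), (10, 100, 50, 1, 20),
         (18.5, 40, 70, 0.75, 18.5 * (40 / 70) ** 0.75)],
    )
    def test_covariate_power(self, tv, cov, med, theta, expected):
        assert covariate_power(tv, cov, med, theta) == pytest.approx(expected, rel=1e-12)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            PopulationModel(cl_typical=-1, v_typical=106, ka=0.861)
        with pytest.raises(ValueError):
            PopulationModel(cl_typical=18.5, v_typical=106, ka=0.861, theta_que=-1.0)
        with pytest.raises(ValueError):
            Subject(subject_id=1, weight=70, quetiapine=2)


class TestSteadyState:
    REG = DosingRegimen(24.5, 12.0)

    def test_trough_value(self):
        # 0.7 mg/kg/day x 70 kg split q12h at the typical subject
        assert conc_steady_state(12.0, self.REG, 18.5, 106, 0.861) == pytest.approx(
            40.7057, abs=2e-3
        )

    def test_zero_dose_everywhere(self):
        reg = DosingRegimen(0.0, 12.0)
        t = np.linspace(0, 12, 25)
        assert np.all(conc_steady_state(t, reg, 18.5, 106, 0.861) == 0.0)

    def test_dose_linearity_exact(self):
        reg2 = DosingRegimen(49.0, 12.0)
        c1 = conc_steady_state(12.0, self.REG, 18.5, 106, 0.861)
        c2 = conc_steady_state(12.0, reg2, 18.5, 106, 0.861)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)
        assert c2 == pytest.approx(81.4, abs=0.1)

    def test_nonnegative_and_decreasing_after_tmax(self):
        ke = 18.5 / 106
        tmax = math.log(0.861 / ke) / (0.861 - ke)
        t = np.linspace(tmax, 12.0, 100)
        c = conc_steady_state(t, self.REG, 18.5, 106, 0.861)
        assert np.all(c >= 0)
        assert np.all(np.diff(c) < 0)

    def test_periodic_trough(self):
        # pre-dose trough equals the value carried over the interval
        c0 = conc_steady_state(0.0, self.REG, 18.5, 106, 0.861)
        ctau = conc_steady_state(12.0, self.REG, 18.5, 106, 0.861)
        assert c0 == pytest.approx(ctau, rel=1e-12)

    def test_time_out_of_interval_rejected(self):
        with pytest.raises(ValueError):
            conc_steady_state(12.5, self.REG, 18.5, 106, 0.861)
        with pytest.raises(ValueError):
            conc_steady_state(-0.1, self.REG, 18.5, 106, 0.861)

    def test_flip_flop_guard_continuity(self):
        # ka ~= ke falls back to the analytic limit; approach must be smooth
        ke = 0.2
        reg = DosingRegimen(10.0, 12.0)
        v = 50.0
        c_lim = conc_steady_state(6.0, reg, ke * v, v, ke * (1 + 1e-9))
        c_near = conc_steady_state(6.0, reg, ke * v, v, ke * (1 + 1e-4))
        assert c_lim == pytest.approx(c_near, rel=1e-3)

    def test_qd_bid_same_daily_average_and_bid_trough_higher(self):
        qd = DosingRegimen(49.0, 24.0)
        bid = DosingRegimen(24.5, 12.0)
        t24 = np.linspace(0, 24, 4801)
        t12 = np.linspace(0, 12, 2401)
        avg_qd = np.trapezoid(conc_steady_state(t24, qd, 18.5, 106, 0.861), t24) / 24
        avg_bid = np.trapezoid(conc_steady_state(t12, bid, 18.5, 106, 0.861), t12) / 12
        assert avg_qd == pytest.approx(avg_bid, rel=1e-6)
        assert conc_steady_state(12.0, bid, 18.5, 106, 0.861) > conc_steady_state(
            24.0, qd, 18.5, 106, 0.861
        )

    @settings(max_examples=30, derandomize=True)
    @given(
        lam=st.floats(0.1, 10.0),
        t=st.floats(0.0, 12.0),
        cl=st.floats(2.0, 40.0),
        v=st.floats(40.0, 300.0),
    )
    def test_dose_linearity_property(self, lam, t, cl, v):
        c1 = conc_steady_state(t, DosingRegimen(10.0, 12.0), cl, v, 0.861)
        c2 = conc_steady_state(t, DosingRegimen(10.0 * lam, 12.0), cl, v, 0.861)
        assert c2 == pytest.approx(lam * c1, rel=1e-9)


class TestSuperposition:
    def test_single_dose_below_steady_state_trough(self):
        c1 = conc_superposition([12.0], [(0.0, 24.5)], 18.5, 106, 0.861)[0]
        css = conc_steady_state(12.0, DosingRegimen(24.5, 12.0), 18.5, 106, 0.861)
        assert 0 < c1 < css

    def test_converges_to_steady_state(self):
        doses = [(12.0 * k, 24.5) for k in range(50)]
        c = conc_superposition([600.0], doses, 18.5, 106, 0.861)[0]
        css = conc_steady_state(12.0, DosingRegimen(24.5, 12.0), 18.5, 106, 0.861)
        assert abs(c - css) / css < 1e-3

    def test_empty_dose_list_is_zero(self):
        assert np.all(conc_superposition([5.0], [], 18.5, 106, 0.861) == 0.0)

    def test_iv_bolus_limit_for_fast_absorption(self):
        # ka -> inf: single oral dose tends to D/V * exp(-ke t)
        ke = 18.5 / 106
        t = np.array([3.0, 8.0])
        c = conc_superposition(t, [(0.0, 24.5)], 18.5, 106, 500.0)
        bolus = 24.5 * 1000 / 106 * np.exp(-ke * t)
        np.testing.assert_allclose(c, bolus, rtol=5e-3)


class TestResidualModel:
    @pytest.mark.parametrize(
        "pred, ep, ea, expected",
        [(40.0, 0.0, 0.0, 40.0), (40.0, 0.1, 0.5, 44.5), (0.0, 0.3, 1.0, 1.0)],
    )
    def test_apply_residual(self, pred, ep, ea, expected):
        assert apply_residual(pred, ep, ea) == pytest.approx(expected, rel=1e-12)

    def test_negative_observations_permitted(self):
        assert apply_residual(1.0, -0.5, -2.0) < 0
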