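"""Non-compartmental estimation against closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gampk.nca import (
    EstimationError,
    LambdaZFit,
    _segment,
    analyze_profile,
    auc_inf,
    auc_last,
    aumc_inf,
    bioavailability,
    dose_normalize,
    fit_lambda_z,
    iv_parameters,
    observed_extrema,
    summarize_group,
)
from gampk.pk_data import Route

from conftest import make_profile

LN2 = math.log(2.0)


class TestFitLambdaZ:
    def test_exact_monoexponential(self):
        times = [24.0, 48.0, 72.0]
        concs = [1000 * math.exp(-0.1 * t) for t in times]
        # prepend an absorption peak so a terminal window exists after Tmax
        p = make_profile([1.0] + times, [2000.0] + concs, lloq=0.0)
        fit = fit_lambda_z(p)
        assert fit.lambda_z == pytest.approx(0.100, rel=1e-10)
        assert fit.t_half == pytest.approx(6.931, abs=5e-4)
        assert fit.r_squared_adj == pytest.approx(1.0, abs=1e-12)
        assert fit.t_half * fit.lambda_z == pytest.approx(LN2, rel=1e-12)

    def test_biexponential_terminal_slope(self):
        # bi-exponential with terminal rate 0.00911/hr; by day 3 the fast
        # phase (0.774/hr) has decayed ~e^-56, so daily samples over days
        # 3-10 are pure terminal decline
        beta = 0.00911
        times = np.arange(72.0, 241.0, 24.0)
        concs = 2950 * np.exp(-0.774 * times) + 18000.0 * np.exp(-beta * times)
        p = make_profile([0.25] + list(times), [20000.0] + list(concs))
        fit = fit_lambda_z(p)
        expected_t_half = LN2 / beta  # 76.09 hr
        assert fit.t_half == pytest.approx(expected_t_half, rel=0.01)

    def test_no_terminal_decline_raises(self):
        p = make_profile([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        with pytest.raises(EstimationError, match="no terminal decline|fewer than 3"):
            fit_lambda_z(p)

    def test_fewer_than_three_points_raises(self):
        p = make_profile([1.0, 2.0, 3.0], [100.0, 50.0, 25.0])
        # only two points lie after Tmax
        with pytest.raises(EstimationError, match="fewer than 3"):
            fit_lambda_z(p)

    def test_manual_window_restricts_points(self):
        times = [1, 24, 48, 72, 96, 120]
        concs = [2000.0] + [1000 * math.exp(-0.05 * t) for t in times[1:]]
        p = make_profile(times, concs)
        fit = fit_lambda_z(p, selection="manual", manual_window=(48.0, 120.0))
        assert fit.n_points == 4
        assert fit.window_start == 48.0
        assert fit.lambda_z == pytest.approx(0.05, rel=1e-9)


class TestAUC:
    def test_constant_curve_is_rectangle(self):
        p = make_profile([0.0, 1.0, 2.0], [100.0, 100.0, 100.0])
        assert auc_last(p) == pytest.approx(200.0)

    def test_log_trapezoid_closed_form(self):
        p = make_profile([0.0, 1.0], [100.0, 50.0])
        assert auc_last(p) == pytest.approx(50.0 / LN2, rel=1e-12)

    def test_dense_grid_matches_analytic_integral(self):
        k, c0, t_end = 0.1, 1000.0, 100.0
        times = np.arange(0.0, t_end + 1e-9, 0.01)
        p = make_profile(times, c0 * np.exp(-k * times), lloq=0.0)
        analytic = c0 / k * (1 - math.exp(-k * t_end))
        assert auc_last(p) == pytest.approx(analytic, rel=1e-3)

    def test_single_point_rejected(self):
        p = make_profile([1.0], [100.0])
        with pytest.raises(EstimationError, match=">= 2"):
            auc_last(p)

    def test_zero_concentration_segment_falls_back_to_linear(self):
        auc, aumc = _segment(0.0, 1.0, 100.0, 0.0)
        assert auc == pytest.approx(50.0)
        assert aumc == pytest.approx(0.0)

    @given(
        st.floats(0.1, 100.0),
        st.floats(0.01, 50.0),
        st.floats(1e-3, 5000.0),
        st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_log_segment_never_exceeds_linear(self, t1, dt, c1, ratio):
        c2 = c1 * ratio  # strictly decreasing segment
        log_auc, _ = _segment(t1, t1 + dt, c1, c2)
        linear_auc = (c1 + c2) / 2.0 * dt
        assert log_auc <= linear_auc * (1 + 1e-12)

    @given(st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_linear_branch_invariant_to_collinear_insertion(self, frac):
        # inserting a point on the chord of an increasing segment leaves
        # the linear-trapezoid area unchanged
        t_mid = frac * 4.0
        c_mid = 100.0 + (300.0 - 100.0) * frac
        base = make_profile([0.0, 4.0], [100.0, 300.0])
        refined = make_profile([0.0, t_mid, 4.0], [100.0, c_mid, 300.0])
        assert auc_last(refined) == pytest.approx(auc_last(base), rel=1e-12)

    def test_additive_over_time_partition(self):
        times = [0.0, 1.0, 2.5, 6.0, 10.0]
        concs = [100.0, 250.0, 120.0, 40.0, 15.0]
        whole = auc_last(make_profile(times, concs, lloq=0.0))
        left = auc_last(make_profile(times[:3], concs[:3], lloq=0.0))
        right = auc_last(make_profile(times[2:], concs[2:], lloq=0.0))
        assert whole == pytest.approx(left + right, rel=1e-12)


class TestExtrapolation:
    def test_tail_arithmetic(self):
        fit = LambdaZFit(0.1, LN2 / 0.1, 3, 48.0, 1.0, 0.0)
        total, frac = auc_inf(90.0, 2.0, fit)
        assert total == pytest.approx(110.0)
        assert frac == pytest.approx(20.0 / 110.0, rel=1e-9)

    def test_zero_clast_identity(self):
        fit = LambdaZFit(0.1, LN2 / 0.1, 3, 48.0, 1.0, 0.0)
        total, frac = auc_inf(90.0, 0.0, fit)
        assert total == 90.0 and frac == 0.0

    def test_invalid_lambda_rejected(self):
        fit = LambdaZFit.__new__(LambdaZFit)
        object.__setattr__(fit, "lambda_z", 0.0)
        with pytest.raises(EstimationError):
            auc_inf(90.0, 2.0, fit)

    def test_truncated_monoexponential_recovers_full_integral(self):
        k, c0 = 0.08, 800.0
        times = np.arange(0.0, 60.0 + 1e-9, 0.05)
        p = make_profile(times, c0 * np.exp(-k * times), lloq=0.0)
        res = analyze_profile(p)
        assert res.auc_inf == pytest.approx(c0 / k, rel=1e-3)
        assert res.aumc_inf == pytest.approx(c0 / k**2, rel=1e-3)


class TestObservedExtrema:
    def test_direct_readout(self):
        p = make_profile([0.083, 1.0, 24.0], [960.0, 400.0, 50.0])
        cmax, tmax, c_last, t_last = observed_extrema(p)
        assert (cmax, tmax) == (960.0, 0.083)
        assert (c_last, t_last) == (50.0, 24.0)

    def test_tie_takes_earlier_time(self):
        p = make_profile([1.0, 2.0, 3.0], [500.0, 500.0, 100.0])
        _, tmax, _, _ = observed_extrema(p)
        assert tmax == 1.0

    def test_single_record_is_both_max_and_last(self):
        p = make_profile([0.5], [100.0])
        cmax, tmax, c_last, t_last = observed_extrema(p)
        assert (cmax, tmax) == (c_last, t_last) == (100.0, 0.5)


class TestIVParameters:
    def _mono_result(self, dose=6.0, c0=1000.0, k=0.1):
        times = np.arange(0.0, 120.0 + 1e-9, 0.02)
        p = make_profile(times, c0 * np.exp(-k * times), dose=dose, lloq=0.0)
        return analyze_profile(p)

    def test_monoexponential_closed_forms(self):
        res = self._mono_result()
        # CL = dose·k/C0 = 600 ml/hr/kg, MRT = 1/k = 10 hr, Vss = 6 L/kg
        assert res.cl_obs == pytest.approx(600.0, rel=2e-3)
        assert res.mrt == pytest.approx(10.0, rel=2e-3)
        assert res.vss == pytest.approx(6.0, rel=4e-3)

    def test_clearance_invariant_to_dose_scaling(self):
        r1 = self._mono_result(dose=6.0, c0=1000.0)
        r2 = self._mono_result(dose=12.0, c0=2000.0)
        assert r2.cl_obs == pytest.approx(r1.cl_obs, rel=1e-9)

    def test_im_route_rejected(self):
        res = self._mono_result()
        bad = res.__class__(**{**res.__dict__, "route": Route.IM})
        with pytest.raises(EstimationError, match="IM"):
            iv_parameters(bad)


class TestRatios:
    def test_bioavailability_group_means(self):
        assert bioavailability(5.43, 6.0, 5.89, 6.0) == pytest.approx(92.19, abs=0.01)
        assert bioavailability(3.15, 3.0, 5.89, 6.0) == pytest.approx(106.96, abs=0.01)

    def test_identity_and_guards(self):
        assert bioavailability(5.0, 6.0, 5.0, 6.0) == 100.0
        with pytest.raises(ValueError):
            bioavailability(0.0, 6.0, 5.0, 6.0)

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_f_invariant_to_unit_rescaling(self, scale):
        f1 = bioavailability(5.43, 6.0, 5.89, 6.0)
        f2 = bioavailability(5.43 * scale, 6.0, 5.89 * scale, 6.0)
        assert f2 == pytest.approx(f1, rel=1e-9)

    def test_dose_normalize(self):
        assert dose_normalize(960.0, 6.0) == pytest.approx(160.0)
        assert dose_normalize(3.15, 3.0) == pytest.approx(1.05)
        assert dose_normalize(7.7, 1.0) == 7.7
        with pytest.raises(ValueError):
            dose_normalize(1.0, 0.0)


class TestGroupSummary:
    def test_hand_arithmetic(self):
        s = summarize_group([1.0, 2.0, 3.0], "IM-6")
        assert s.mean == 2.0 and s.sd == pytest.approx(1.0)
        assert s.formatted == "2.00 ± 1.00"

    def test_single_value_omits_sd(self):
        s = summarize_group([5.43], "IM-6")
        assert s.sd is None and s.formatted == "5.43"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        values = rng.lognormal(8.5, 0.2, size=6)
        s = summarize_group(list(values), "g")
        assert s.mean == pytest.approx(sum(values) / 6)
        brute_sd = math.sqrt(sum((v - s.mean) ** 2 for v in values) / 5)
        assert s.sd == pytest.approx(brute_sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([], "g")
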