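"""Baseline band, hit-criteria chain, MDT, AUC and the abundance control."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from cetsakit import (BaselineBand, LL4Params, abundance_control,
                      auc_summary, baseline_band, call_hit, compute_mdt,
                      fit_ll4, ll4_eval)
from cetsakit.curve_models import LL4Fit
from cetsakit.errors import DataError
from cetsakit.itdr_hits import pseudo_dose_grid
from cetsakit.synth_data import dosed_tm, soluble_fraction

from conftest import DOSES, make_curve


def band_from_values(values, **kw):
    """Feed crafted pooled values through baseline_band via channels 1..2."""
    curves = []
    for i in range(0, len(values), 2):
        fc = np.full(10, np.nan)
        fc[0] = 1.0
        fc[1] = values[i]
        if i + 1 < len(values):
            fc[2] = values[i + 1]
        curves.append(make_curve(fc, protein_id=f"P{i}"))
    kw.setdefault("min_pool", 1)
    return baseline_band(curves, **kw)


def good_fit(params, x=None, y=None):
    return LL4Fit(params=params, r_squared=0.99, n_points=10, converged=True,
                  residual_sum_squares=1e-4)


class TestBaselineBand:
    def test_constant_pool_gives_zero_width(self):
        band = band_from_values([1.0] * 5)
        assert (band.pooled_median, band.mad) == (1.0, 0.0)
        assert band.lower == band.upper == 1.0
        assert band.degenerate

    def test_hand_computed_mad_case(self):
        # median 1.0; |dev| = {0.1, 0, 0.1, 0, 0} whose median is 0 -> band [1,1]
        band = band_from_values([0.9, 1.0, 1.1, 1.0, 1.0])
        assert band.pooled_median == 1.0
        assert band.mad == 0.0

    def test_monte_carlo_band_matches_normal_theory(self):
        rng = np.random.default_rng(123)
        n = 5000
        sigma = 0.08
        curves = []
        for i in range(n):
            fc = np.exp(sigma * rng.standard_normal(10))
            fc[0] = 1.0
            curves.append(make_curve(fc, protein_id=f"P{i}"))
        band = baseline_band(curves)
        sigma_hat = band.mad  # scaled MAD estimates the pooled sd
        assert band.upper == pytest.approx(band.pooled_median + 2.5 * sigma_hat)
        assert sigma_hat == pytest.approx(sigma, rel=0.08)
        pooled = np.concatenate([c.fold_changes[[1, 2]] for c in curves])
        frac_out = np.mean((pooled < band.lower) | (pooled > band.upper))
        expect = 2 * norm.cdf(-2.5)  # ~1.2%
        assert frac_out == pytest.approx(expect, rel=0.5)

    def test_reference_entries_do_not_dilute_the_pool(self):
        rng = np.random.default_rng(7)
        curves = []
        for i in range(1000):
            fc = np.exp(0.1 * rng.standard_normal(10))
            fc[0] = 1.0
            curves.append(make_curve(fc, protein_id=f"P{i}"))
        excl = baseline_band(curves, exclude_reference=True)
        incl = baseline_band(curves, exclude_reference=False)
        assert excl.n_values == 2000 and incl.n_values == 3000
        assert incl.mad < excl.mad  # constant 1s shrink the estimate

    def test_too_small_pool_is_an_error(self):
        with pytest.raises(DataError, match="pooled"):
            band_from_values([1.0] * 5, min_pool=30)


class TestCallHit:
    BAND = BaselineBand(pooled_median=1.0, mad=0.02, lower=0.95, upper=1.05,
                        n_values=1000)

    def test_flat_curve_is_not_a_hit(self):
        curve = make_curve(np.ones(10))
        fit = fit_ll4(pseudo_dose_grid(curve.x_values), curve.fold_changes)
        call = call_hit(curve, fit, self.BAND, psm=5)
        assert call.direction == "none"
        assert not call.pass_baseline and not call.pass_30pct

    def _stabilized_curve(self):
        params = LL4Params(b=-1.5, c=1.0, d=1.8, e=100.0)
        fc = ll4_eval(params, DOSES)
        fc[0] = 1.0
        return make_curve(fc), params

    def test_stabilized_example_passes_every_rule(self):
        curve, params = self._stabilized_curve()
        fit = fit_ll4(pseudo_dose_grid(curve.x_values), curve.fold_changes)
        call = call_hit(curve, fit, self.BAND, psm=5)
        # hand check: top-3 max ~1.8 >= 1.3*1.05 = 1.365; R^2 ~1 > 0.8; psm 5 >= 3
        assert call.direction == "stabilized"
        assert call.pass_baseline and call.pass_30pct and call.pass_r2 and call.pass_psm
        assert call.mdt is not None

    def test_psm_veto_blocks_otherwise_perfect_hit(self):
        curve, _ = self._stabilized_curve()
        fit = fit_ll4(pseudo_dose_grid(curve.x_values), curve.fold_changes)
        call = call_hit(curve, fit, self.BAND, psm=2)
        assert call.direction == "none"
        assert not call.pass_psm
        assert call.pass_baseline and call.pass_30pct and call.pass_r2

    def test_destabilized_branch(self):
        params = LL4Params(b=1.5, c=0.5, d=1.0, e=100.0)
        fc = ll4_eval(params, DOSES)
        fc[0] = 1.0
        curve = make_curve(fc)
        fit = fit_ll4(pseudo_dose_grid(curve.x_values), curve.fold_changes)
        call = call_hit(curve, fit, self.BAND, psm=5)
        assert call.direction == "destabilized"

    def test_call_is_deterministic(self):
        curve, _ = self._stabilized_curve()
        fit = fit_ll4(pseudo_dose_grid(curve.x_values), curve.fold_changes)
        a = call_hit(curve, fit, self.BAND, psm=5)
        b = call_hit(curve, fit, self.BAND, psm=5)
        assert a == b


class TestComputeMdt:
    BAND = BaselineBand(pooled_median=1.0, mad=0.04, lower=0.9, upper=1.1,
                        n_values=1000)

    def test_closed_form_crossing(self):
        # 10*exp(-0.5*ln 9) = 10/3
        fit = good_fit(LL4Params(b=-2, c=1.0, d=2.0, e=10.0))
        mdt, flags = compute_mdt(fit, self.BAND, (0.1, 25000), "stabilized")
        assert mdt == pytest.approx(10.0 / 3.0, rel=1e-9)
        assert flags == []

    def test_bisection_cross_check(self):
        fit = good_fit(LL4Params(b=-2, c=1.0, d=2.0, e=10.0))
        mdt, _ = compute_mdt(fit, self.BAND, (0.1, 25000), "stabilized")
        lo, hi = 0.1, 25000.0
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if ll4_eval(fit.params, mid) < 1.1:
                lo = mid
            else:
                hi = mid
        assert mdt == pytest.approx(math.sqrt(lo * hi), rel=1e-9)

    def test_saturated_curve_clips_to_lowest_dose(self):
        fit = good_fit(LL4Params(b=-2, c=1.5, d=2.0, e=1.0))  # entirely above upper
        mdt, flags = compute_mdt(fit, self.BAND, (0.1, 25000), "stabilized")
        assert mdt == pytest.approx(0.1)
        assert "saturated" in flags

    def test_curve_never_crossing_returns_none(self):
        fit = good_fit(LL4Params(b=-2, c=1.0, d=1.05, e=10.0))  # tops out below 1.1
        mdt, _ = compute_mdt(fit, self.BAND, (0.1, 25000), "stabilized")
        assert mdt is None

    def test_degenerate_band_uses_epsilon_edge_and_flags(self):
        band = BaselineBand(pooled_median=1.0, mad=0.0, lower=1.0, upper=1.0,
                            n_values=10)
        fit = good_fit(LL4Params(b=-2, c=1.0, d=2.0, e=10.0))
        mdt, flags = compute_mdt(fit, band, (0.1, 25000), "stabilized")
        assert "degenerate_band" in flags
        # crossing of 1.01: 10*((2-1.01)/(0.01))^(-1/2)
        assert mdt == pytest.approx(10.0 * (99.0) ** -0.5, rel=1e-9)

    def test_monotone_in_ec50(self):
        # a lower true EC50 never yields a larger MDT (noiseless curves)
        band = self.BAND
        mdts = []
        for kd in [1.0, 4.0, 16.0, 64.0, 256.0, 1024.0]:
            tm = dosed_tm(50.0, DOSES, kd, 4.0)
            fc = soluble_fraction(tm, 0.8, 0.1, 52.0) / soluble_fraction(50.0, 0.8, 0.1, 52.0)
            fit = fit_ll4(pseudo_dose_grid(DOSES), fc)
            mdt, _ = compute_mdt(fit, band, (DOSES[0], DOSES[-1]), "stabilized")
            mdts.append(mdt)
        assert all(m is not None for m in mdts)
        assert all(a <= b * (1 + 1e-9) for a, b in zip(mdts, mdts[1:]))


class TestAucSummary:
    def test_flat_curve_is_zero(self):
        assert auc_summary(make_curve(np.ones(10))) == pytest.approx(0.0)

    def test_constant_excess_is_that_excess(self):
        assert auc_summary(make_curve(np.full(10, 1.5))) == pytest.approx(0.5)

    def test_matches_fine_grid_quadrature(self):
        rng = np.random.default_rng(5)
        fc = np.exp(0.2 * rng.standard_normal(10))
        curve = make_curve(fc)
        lx = np.log10(DOSES)
        fine = np.linspace(lx[0], lx[-1], 20001)
        y = np.interp(fine, lx, fc - 1.0)
        oracle = np.trapezoid(y, fine) / (lx[-1] - lx[0])
        assert auc_summary(curve) == pytest.approx(oracle, abs=1e-6)


class TestPseudoDose:
    def test_zero_maps_one_ladder_step_below(self):
        x = np.array([0.0, 1.0, 4.0, 16.0])
        out = pseudo_dose_grid(x)
        assert out[0] == pytest.approx(0.25)
        np.testing.assert_allclose(out[1:], x[1:])

    def test_all_positive_grid_unchanged(self):
        np.testing.assert_allclose(pseudo_dose_grid(DOSES), DOSES)


class TestAbundanceControl:
    def test_examples(self):
        flags = abundance_control([("A", 1.0), ("B", 1.25), ("C", 2.0)],
                                  [("A", 1.0), ("B", 1.0), ("D", 1.0)])
        by = {f.protein_id: f for f in flags}
        assert not by["A"].flagged
        assert by["B"].flagged and by["B"].ratio == pytest.approx(1.25)
        assert by["C"].reason == "unassessable"

    def test_null_flag_rate_matches_normal_theory(self):
        # two 5%-CV lognormal measurements -> ratio log-sd 0.05*sqrt(2);
        # flagged fraction must match the two-sided tail beyond +/-10%
        rng = np.random.default_rng(77)
        n = 5000
        treated = [(f"P{i}", float(np.exp(0.05 * rng.standard_normal())))
                   for i in range(n)]
        control = [(f"P{i}", float(np.exp(0.05 * rng.standard_normal())))
                   for i in range(n)]
        flags = abundance_control(treated, control, tolerance=0.10)
        frac = np.mean([f.flagged for f in flags])
        s = 0.05 * math.sqrt(2)
        expect = (1 - norm.cdf(math.log(1.1) / s)) + norm.cdf(math.log(0.9) / s)
        assert frac == pytest.approx(expect, rel=0.15)
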