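"""Wald ratios, IVW, Egger, weighted median, mode-based estimate, heterogeneity."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from mr2s import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    SingularDesignError,
    WaldRatio,
    cochran_q,
    egger,
    i2_gx,
    ivw,
    mode_based_estimate,
    report_per_sd_decrease,
    wald_ratios,
    weighted_median,
)
from mr2s.estimators import _egger_fit, _kde_mode, _mode_bandwidth, _weighted_median


def ratios_of(thetas, se=0.1):
    return [WaldRatio(f"rs{i}", float(t), se) for i, t in enumerate(thetas)]


class TestWaldRatios:
    @pytest.mark.parametrize(
        "bx,by,sy,theta,se",
        [
            (0.05, 0.01, 0.005, 0.2, 0.1),
            (-0.05, 0.01, 0.005, -0.2, 0.1),  # sign carried by the exposure effect
            (0.05, 0.0, 0.005, 0.0, 0.1),     # null instrument, finite se
        ],
    )
    def test_ratio_and_delta_method_se(self, make_instruments, bx, by, sy, theta, se):
        iset = make_instruments([bx], [by], sy=[sy])
        (r,) = wald_ratios(iset)
        assert r.theta == pytest.approx(theta)
        assert r.se == pytest.approx(se)

    def test_zero_exposure_effect_is_an_error(self, make_instruments):
        iset = make_instruments([0.0], [0.01])
        with pytest.raises(DegenerateInstrumentError, match="rs0000"):
            wald_ratios(iset)


class TestIVW:
    def test_single_ratio_reduces_to_wald(self):
        est = ivw(ratios_of([0.2]), model="random")
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_closed_form_weighted_mean(self):
        est = ivw(ratios_of([0.1, 0.2, 0.3]), model="fixed")
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1 / np.sqrt(3))
        assert est.q == pytest.approx(2.0)
        assert est.overdispersion == 1.0

    def test_equals_weighted_mean_and_wls_slope_oracles(self, make_instruments):
        # on <=10 instruments IVW must equal both independent closed forms
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.02, 0.08, 10)
        by = 0.2 * bx + rng.normal(0, 0.01, 10)
        sy = rng.uniform(0.005, 0.02, 10)
        iset = make_instruments(bx, by, sy=sy)
        est = ivw(wald_ratios(iset), model="fixed")
        t = by / bx
        w = (bx / sy) ** 2
        assert est.theta == pytest.approx(np.sum(w * t) / np.sum(w), abs=1e-12)
        wls = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert est.theta == pytest.approx(wls.params[0], abs=1e-12)

    @given(
        thetas=st.lists(st.floats(-1, 1), min_size=2, max_size=8),
        se=st.floats(0.05, 0.5),
    )
    def test_random_effects_se_never_below_fixed(self, thetas, se):
        r = ratios_of(thetas, se)
        est_f = ivw(r, model="fixed")
        est_r = ivw(r, model="random")
        assert est_r.se >= est_f.se
        # equality iff Q <= J-1
        assert (est_r.se == est_f.se) == (est_r.q <= len(r) - 1)

    def test_penalization_downweights_heterogeneous_ratio(self):
        base = ratios_of([0.2] * 10 + [2.0])
        plain = ivw(base, model="fixed")
        pen = ivw(base, model="fixed", penalized=True)
        assert abs(pen.theta - 0.2) < abs(plain.theta - 0.2)


class TestCochranQ:
    def test_identical_ratios_have_zero_q(self):
        q, df, p = cochran_q(ratios_of([0.2, 0.2, 0.2]), 0.2)
        assert q == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        q, df, p = cochran_q(ratios_of([0.1, 0.2, 0.3]), 0.2)
        assert (q, df) == (pytest.approx(2.0), 2)
        assert p == pytest.approx(np.exp(-1.0), rel=1e-6)  # chi2_2 survival at 2


class TestEgger:
    def test_two_point_exact_line(self):
        # fitted without the J>=3 guard via the low-level fit
        intercept, slope, _, rss = _egger_fit(
            np.array([0.1, 0.2]), np.array([0.03, 0.04]), np.array([1e4, 1e4])
        )
        assert slope == pytest.approx(0.1)
        assert intercept == pytest.approx(0.02)
        assert rss == pytest.approx(0.0, abs=1e-20)

    def test_identical_exposure_effects_raise(self, make_instruments):
        iset = make_instruments([0.05] * 5, [0.01] * 5)
        with pytest.raises(SingularDesignError):
            egger(iset)

    def test_fewer_than_three_instruments_raise(self, make_instruments):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_instruments([0.1, 0.2], [0.01, 0.02]))

    def test_matches_statsmodels_wls_oracle(self, make_instruments):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.02, 0.08, 10)
        by = 0.01 + 0.2 * bx + rng.normal(0, 0.01, 10)
        sy = rng.uniform(0.005, 0.02, 10)
        iset = make_instruments(bx, by, sy=sy)
        est = egger(iset, model="fixed")
        wls = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert est.theta == pytest.approx(wls.params[1], abs=1e-10)
        assert est.egger_intercept == pytest.approx(wls.params[0], abs=1e-10)
        # statsmodels scales the covariance by the residual MSE; undo to
        # compare against the unscaled weighted-least-squares covariance
        unscaled = wls.bse / np.sqrt(wls.mse_resid)
        assert est.egger_intercept_se == pytest.approx(unscaled[0], rel=1e-8)
        assert est.se == pytest.approx(unscaled[1], rel=1e-8)

    def test_invariant_to_allele_sign_convention(self, make_instruments):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.02, 0.08, 8)
        by = 0.005 + 0.3 * bx + rng.normal(0, 0.005, 8)
        flip = np.array([1, -1] * 4, dtype=float)
        a = egger(make_instruments(bx, by))
        b = egger(make_instruments(bx * flip, by * flip))
        assert b.theta == pytest.approx(a.theta)
        assert b.egger_intercept == pytest.approx(a.egger_intercept)
        assert b.i2_gx == pytest.approx(a.i2_gx)

    def test_i2_gx_formula(self, make_instruments):
        bx = np.array([0.02, 0.04, 0.06])
        sx = np.array([0.004, 0.005, 0.006])
        iset = make_instruments(bx, bx * 0.1, sx=sx)
        wx = sx**-2.0
        mean_w = np.sum(wx * bx) / np.sum(wx)
        q_gx = np.sum((bx - mean_w) ** 2 / sx**2)
        assert i2_gx(iset) == pytest.approx((q_gx - 2) / q_gx)


class TestWeightedMedian:
    def test_odd_equal_weights_is_middle_value(self, make_instruments):
        assert _weighted_median(np.array([1.0, 2.0, 3.0]), np.ones(3)) == 2.0

    def test_even_equal_weights_interpolates(self):
        # s grid 0.125/0.375/0.625/0.875 -> interpolation at 0.5 gives 2.5
        assert _weighted_median(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4)) == 2.5

    @given(
        thetas=st.lists(
            st.floats(-5, 5), min_size=3, max_size=9,
        ).filter(lambda v: len(v) % 2 == 1)
    )
    def test_equal_weights_reduce_to_ordinary_median(self, thetas):
        t = np.array(thetas)
        assert _weighted_median(t, np.ones(t.size)) == pytest.approx(
            float(np.median(t))
        )

    def test_bootstrap_se_is_seeded_and_reproducible(self, make_instruments):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.02, 0.08, 10)
        by = 0.2 * bx + rng.normal(0, 0.01, 10)
        iset = make_instruments(bx, by)
        a = weighted_median(iset, n_boot=200, seed=42)
        b = weighted_median(iset, n_boot=200, seed=42)
        assert a == b
        assert a.se > 0


class TestModeBasedEstimate:
    def test_degenerate_identical_ratios(self, make_instruments):
        iset = make_instruments([0.05, 0.1, 0.2], [0.01, 0.02, 0.04])
        with pytest.warns(UserWarning, match="identical"):
            est = mode_based_estimate(iset, seed=1, n_boot=10)
        assert est.theta == pytest.approx(0.2)
        assert est.se == 0.0

    def test_bimodal_mode_matches_dense_grid_oracle(self, make_instruments):
        # ratios {0, 0, 0, 0.5}: the mode sits near 0
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.0, 0.0, 0.0, 0.05])
        iset = make_instruments(bx, by)
        est = mode_based_estimate(iset, phi=1.0, n_boot=10, seed=1)
        th = by / bx
        h = _mode_bandwidth(th, 1.0)
        grid = np.arange(th.min() - 3 * h, th.max() + 3 * h, 1e-4)
        dens = np.exp(-0.5 * ((grid[:, None] - th[None, :]) / h) ** 2).sum(axis=1)
        oracle = grid[dens.argmax()]
        assert abs(est.theta - oracle) < 1e-4
        assert abs(est.theta) < h  # near zero relative to the kernel scale


class TestPerSDDecreaseScale:
    def test_null_maps_to_unit_odds_ratio(self):
        est = ivw(ratios_of([0.0, 0.0]), model="fixed")
        assert est.or_per_sd_decrease == pytest.approx(1.0)

    def test_reported_odds_ratio_and_interval(self):
        # theta -0.0889 with CI (-0.334, 0.157) on the per-SD-increase scale
        est = ivw(ratios_of([-0.0889]), model="fixed")
        object.__setattr__(est, "ci_low", -0.334)
        object.__setattr__(est, "ci_high", 0.157)
        out = report_per_sd_decrease(est)
        assert out.or_per_sd_decrease == pytest.approx(1.093, abs=5e-4)
        assert out.or_ci_low == pytest.approx(0.855, abs=5e-4)
        assert out.or_ci_high == pytest.approx(1.396, abs=5e-3)
        assert out.or_ci_low < out.or_ci_high
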