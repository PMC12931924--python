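"""RoG size-tuning fits, RF/surround extraction, SI, canonical values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamvar.tuning import (DoubleRoGParams, RoGParams, canonical_size_values,
                           correlate_ff_change_with_si, fit_double_rog,
                           fit_rate_rog, population_average, rf_diameter, rog,
                           rog_sum, size_grid, suppression_index,
                           surround_diameter)

P_REF = RoGParams(k_c=30.0, w_c=0.9, k_s=2.0, w_s=4.0, r0=4.0)


class TestRogCurve:
    def test_zero_diameter_gives_offset(self):
        assert rog(0.0, P_REF) == pytest.approx(P_REF.r0)

    def test_no_surround_is_monotone(self):
        p = RoGParams(k_c=20.0, w_c=1.0, k_s=0.0, w_s=4.0, r0=2.0)
        g = size_grid(0.05, 26.0, 300)
        assert np.all(np.diff(rog(g, p)) >= -1e-12)

    def test_large_size_plateau_matches_limit(self):
        val = rog(1e6, P_REF)
        assert val == pytest.approx(P_REF.r0 + P_REF.k_c / (1 + P_REF.k_s), rel=1e-9)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            RoGParams(k_c=-1.0, w_c=1.0, k_s=0.0, w_s=1.0)
        with pytest.raises(ValueError):
            RoGParams(k_c=1.0, w_c=0.0, k_s=0.0, w_s=1.0)


class TestRateFit:
    diam = np.geomspace(0.1, 26.0, 12)

    def test_noiseless_self_consistency(self):
        rates = rog(self.diam, P_REF)
        fit = fit_rate_rog(self.diam, rates, seed=0)
        dense = size_grid()
        rmse = np.sqrt(np.mean((rog(dense, fit) - rog(dense, P_REF)) ** 2))
        assert rmse < 0.01 * rog(dense, P_REF).max()
        assert rf_diameter(fit) == pytest.approx(rf_diameter(P_REF), rel=0.05)

    def test_constant_rates_flagged_flat(self):
        fit = fit_rate_rog(self.diam, np.full(self.diam.size, 7.0), seed=0)
        assert rf_diameter(fit) is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit_rate_rog(self.diam[:4], np.ones(4))

    def test_noisy_rf_recovery(self):
        """5% multiplicative noise: median RF error across replicates small."""
        rf_true = rf_diameter(P_REF)
        errs = []
        for i in range(30):
            r = np.random.default_rng(i)
            rates = rog(self.diam, P_REF) * (1 + 0.05 * r.standard_normal(12))
            fit = fit_rate_rog(self.diam, rates, seed=i)
            rf = rf_diameter(fit)
            if rf is not None:
                errs.append(abs(rf - rf_true) / rf_true)
        assert np.median(errs) < 0.15


class TestDoubleRogFit:
    diam = np.geomspace(0.1, 26.0, 12)

    def test_self_consistency_on_known_curve(self):
        truth = DoubleRoGParams(
            a=RoGParams(k_c=2.0, w_c=0.8, k_s=1.5, w_s=3.0, r0=1.2),
            b=RoGParams(k_c=1.0, w_c=8.0, k_s=0.5, w_s=20.0, r0=0.0))
        vals = rog_sum(self.diam, truth)
        fit = fit_double_rog(self.diam, vals, seed=0)
        dense = size_grid(0.1, 26.0, 200)
        rmse = np.sqrt(np.mean((rog_sum(dense, fit) - rog_sum(dense, truth)) ** 2))
        assert rmse < 0.02 * np.abs(rog_sum(dense, truth)).max()

    def test_u_shape_extrema_recovered(self):
        """A dip at the RF with a far-surround rise is the characteristic
        variability profile; the fit must place both extrema correctly."""
        dip, rise = 1.0, 26.0
        vals = 2.0 - 0.8 * np.exp(-((np.log(self.diam / dip)) ** 2) / 0.8) \
            + 0.8 * (self.diam / 26.0) ** 1.5
        fit = fit_double_rog(self.diam, vals, seed=0)
        dense = size_grid(0.1, 26.0, 500)
        curve = rog_sum(dense, fit)
        i_min = np.argmin(curve)
        assert dense[i_min] == pytest.approx(dip, rel=0.6)
        assert curve[-1] > curve[i_min] + 0.4    # far rise present

    def test_constant_values_fit_flat(self):
        fit = fit_double_rog(self.diam, np.full(12, 2.0), seed=0)
        dense = size_grid(0.1, 26.0, 300)
        curve = rog_sum(dense, fit)
        assert (curve.max() - curve.min()) < 0.05 * curve.mean()

    def test_nonfinite_rejected(self):
        vals = np.ones(12)
        vals[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_double_rog(self.diam, vals)


class TestRfAndSurround:
    def test_saturating_curve_has_undefined_rf(self):
        p = RoGParams(k_c=20.0, w_c=1.0, k_s=0.0, w_s=4.0, r0=2.0)
        assert rf_diameter(p) is None

    def test_rf_matches_brute_force_argmax(self):
        grid = size_grid()
        rf = rf_diameter(P_REF)
        assert rf == pytest.approx(grid[np.argmax(rog(grid, P_REF))])

    def test_plateau_tie_breaks_to_smallest(self):
        def plateau(s):
            return np.clip(s, None, 1.0) - 0.2 * np.clip(s - 2.0, 0.0, None)

        assert rf_diameter(plateau) == pytest.approx(1.0, rel=0.01)

    def test_surround_undefined_without_suppression(self):
        p = RoGParams(k_c=20.0, w_c=1.0, k_s=0.05, w_s=30.0, r0=2.0)
        rf = rf_diameter(p)
        if rf is not None:
            s, defined = surround_diameter(p, rf)
            assert not defined and s == 26.0

    def test_surround_matches_fine_grid_scan(self):
        rf = rf_diameter(P_REF)
        s_coarse, ok = surround_diameter(P_REF, rf)
        assert ok
        s_fine, _ = surround_diameter(P_REF, rf, grid=size_grid(n=20_000))
        assert s_coarse == pytest.approx(s_fine, rel=0.02)

    @pytest.mark.parametrize("k_s", [0.5, 1.0, 2.0, 5.0])
    def test_surround_never_below_rf(self, k_s):
        p = RoGParams(k_c=30.0, w_c=0.9, k_s=k_s, w_s=4.0, r0=4.0)
        rf = rf_diameter(p)
        if rf is None:
            return
        s, _ = surround_diameter(p, rf)
        assert s >= rf


class TestSuppressionIndex:
    def test_limits_and_arithmetic(self):
        class Fixed:
            def __init__(self, r_rf, r_sur):
                self.r_rf, self.r_sur = r_rf, r_sur

            def __call__(self, s):
                s = np.atleast_1d(s)
                return np.where(s >= 26.0, self.r_sur, self.r_rf)

        assert suppression_index(Fixed(10.0, 10.0), rf=1.0) == 0.0
        assert suppression_index(Fixed(10.0, 0.0), rf=1.0) == 1.0
        assert suppression_index(Fixed(10.0, 4.0), rf=1.0) == pytest.approx(0.6)

    @settings(max_examples=20, deadline=None)
    @given(c=st.floats(min_value=0.1, max_value=50.0))
    def test_invariant_to_curve_rescaling(self, c):
        scaled = RoGParams(k_c=c * P_REF.k_c, w_c=P_REF.w_c, k_s=P_REF.k_s,
                           w_s=P_REF.w_s, r0=c * P_REF.r0)
        rf = rf_diameter(P_REF)
        assert suppression_index(scaled, rf=rf) == pytest.approx(
            suppression_index(P_REF, rf=rf), rel=1e-6)


class TestCanonicalAndPopulation:
    def test_normalisation_at_rf_is_one(self):
        rf = rf_diameter(P_REF)
        sizes, vals, flags = canonical_size_values(P_REF, rf, s_min=0.1)
        assert vals["rf"] == 1.0
        assert sizes["rf"] == rf
        assert sizes["26"] == 26.0

    def test_constant_curve_all_ones(self):
        sizes, vals, _ = canonical_size_values(lambda s: np.full_like(s, 3.0),
                                               rf=1.0, s_min=0.1)
        assert all(v == pytest.approx(1.0) for v in vals.values())

    def test_large_rf_multiples_clipped_and_flagged(self):
        _, _, flags = canonical_size_values(P_REF, rf=5.0, s_min=0.1)
        assert any("clipped" in f for f in flags)

    def test_identical_units_geometric_mean(self):
        vals = np.tile([1.0, 0.5, 2.0], (6, 1))
        gmean, sd = population_average(vals, seed=0)
        assert np.allclose(gmean, [1.0, 0.5, 2.0])
        assert np.allclose(sd, 0.0)

    def test_geometric_mean_of_one_and_four_is_two(self):
        gmean, _ = population_average(np.array([[1.0], [4.0]]), seed=0)
        assert gmean[0] == pytest.approx(2.0)

    def test_lognormal_sample_recovers_exp_mu(self, rng):
        vals = rng.lognormal(mean=0.3, sigma=0.5, size=(400, 1))
        gmean, sd = population_average(vals, seed=0)
        assert abs(gmean[0] - np.exp(0.3)) < 4 * sd[0]

    def test_nonpositive_unit_excluded_with_warning(self):
        vals = np.array([[1.0, 2.0], [0.0, 3.0], [4.0, 5.0]])
        with pytest.warns(UserWarning, match="excluding"):
            gmean, _ = population_average(vals, seed=0)
        assert gmean[0] == pytest.approx(2.0)  # geomean of 1 and 4


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = correlate_ff_change_with_si(2 * x, x)
        assert res["r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_anticorrelated(self):
        x = np.arange(8.0)
        assert correlate_ff_change_with_si(-x, x)["r"] == pytest.approx(-1.0)

    def test_null_pairs_small_r(self):
        rs = []
        for i in range(200):
            r = np.random.default_rng(i)
            rs.append(correlate_ff_change_with_si(r.standard_normal(30),
                                                  r.standard_normal(30))["r"])
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_ff_change_with_si(np.ones(6), np.arange(6.0))
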