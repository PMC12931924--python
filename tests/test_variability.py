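"""Fano-factor machinery, bootstrap tests, classification, mean matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamvar.variability import (bootstrap_sd, classify_unit_modulation,
                                fano_factor, mean_matched_fano, median_zero_test,
                                remove_outliers_mad, sliding_fano)


class TestFano:
    def test_constant_counts_zero(self):
        assert fano_factor([2, 2, 2, 2]).ff == 0.0

    def test_all_zero_counts_zero(self):
        assert fano_factor([0, 0, 0, 0]).ff == 0.0

    def test_poisson_near_one(self, rng):
        counts = rng.poisson(5, 10_000)
        assert 0.95 <= fano_factor(counts).ff <= 1.05

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            fano_factor([3])

    @settings(max_examples=20, deadline=None)
    @given(perm_seed=st.integers(0, 10_000))
    def test_trial_permutation_invariance(self, perm_seed):
        counts = np.random.default_rng(5).poisson(4, 50)
        perm = np.random.default_rng(perm_seed).permutation(counts)
        assert fano_factor(perm).ff == pytest.approx(fano_factor(counts).ff)

    def test_integer_scaling_scales_ff(self):
        # var(c x)/mean(c x) = c * var/mean
        counts = np.random.default_rng(6).poisson(4, 200)
        c = 3
        assert fano_factor(c * counts).ff == pytest.approx(
            c * fano_factor(counts).ff, rel=1e-6)


class TestSlidingFano:
    def test_stationary_poisson_flat_near_one(self, rng):
        trials = [np.sort(rng.uniform(-400, 500, rng.poisson(45)))
                  for _ in range(400)]
        centers, ffs = sliding_fano(trials, -400.0, 500.0, window_ms=100.0,
                                    step_ms=50.0)
        assert abs(ffs.mean() - 1.0) < 0.1
        assert np.ptp(ffs) < 0.5

    def test_matches_direct_counting(self, rng):
        trials = [np.sort(rng.uniform(-400, 500, 40)) for _ in range(20)]
        centers, ffs = sliding_fano(trials, -400.0, 500.0, window_ms=100.0,
                                    step_ms=100.0)
        s0 = centers[3] - 50.0
        counts = np.array([np.count_nonzero((t >= s0) & (t < s0 + 100.0))
                           for t in trials])
        assert ffs[3] == pytest.approx(fano_factor(counts).ff)

    def test_non_overlapping_window_count(self):
        trials = [np.array([0.0]), np.array([1.0])]
        centers, _ = sliding_fano(trials, 0.0, 500.0, window_ms=100.0, step_ms=100.0)
        assert centers.size == 5

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValueError, match="[Ww]indow"):
            sliding_fano([np.array([1.0])] * 3, 0.0, 50.0, window_ms=100.0,
                         step_ms=10.0)


class TestBootstrapSd:
    def test_constant_counts_zero_sd(self):
        assert bootstrap_sd(lambda c: c.mean(), np.full(50, 3.0), B=200) == 0.0

    def test_mean_statistic_matches_standard_error(self, rng):
        x = rng.standard_normal(100)
        sd = bootstrap_sd(lambda c: c.mean(), x, B=2000, seed=1)
        assert sd == pytest.approx(x.std(ddof=1) / 10.0, rel=0.15)

    def test_stable_under_doubling_B(self, rng):
        x = rng.poisson(5, 60).astype(float)
        s1 = bootstrap_sd(lambda c: c.mean(), x, B=2000, seed=2)
        s2 = bootstrap_sd(lambda c: c.mean(), x, B=4000, seed=3)
        assert abs(s1 - s2) / s1 < 0.10


class TestMedianZeroTest:
    def test_symmetric_sample_p_near_half(self):
        x = np.r_[np.ones(10), -np.ones(10), 1e-6]
        p = median_zero_test(x, B=4999, tail="greater", seed=0)
        assert 0.3 < p < 0.7

    def test_large_uniform_shift_hits_floor(self):
        B = 9999
        p = median_zero_test(np.full(20, 10.0) + 1e-9 * np.arange(20), B=B,
                             tail="greater", seed=0)
        assert p == pytest.approx(1.0 / (B + 1))

    def test_null_p_values_calibrated(self):
        # reduced version of the full type-I simulation (acceptance covers 500)
        rej = 0
        n_sim = 200
        for i in range(n_sim):
            x = np.random.default_rng(50_000 + i).standard_normal(41)
            rej += median_zero_test(x, B=1999, tail="greater", seed=i) < 0.05
        sd = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) < 4 * sd

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_zero_test(np.full(10, 1.0))


class TestClassification:
    def test_no_modulation_all_ns(self, rng):
        base = rng.poisson(5, 200).astype(float)
        conds = [rng.poisson(5, 200).astype(float) for _ in range(5)]
        lab = classify_unit_modulation(conds, base, B=3000, seed=0)
        assert lab.unit_class == "neither"
        assert all(f == "ns" for f in lab.flags)

    def test_amplifier_detected(self):
        """FF above baseline at small sizes, below at the RF, flags both and
        classifies the unit as an amplifier in at least 90% of 100 runs."""
        hits = 0
        n_runs = 100
        sig = 0.6
        for i in range(n_runs):
            r = np.random.default_rng(200 + i)
            n = 100
            gain = lambda size: np.exp(sig * r.standard_normal(size) - sig**2 / 2)
            base = r.poisson(2.5 * gain(n))      # FF ~ 2.1
            small = r.poisson(30.0 * gain(n))    # FF ~ 14: amplification
            at_rf = r.poisson(12.0, n)           # FF ~ 1: quenching
            lab = classify_unit_modulation([small.astype(float), at_rf.astype(float)],
                                           base.astype(float), B=3000, seed=i)
            hits += lab.unit_class == "amplifier"
        assert hits / n_runs >= 0.9

    def test_pure_quencher_rarely_misclassified(self):
        amps = 0
        n_runs = 50
        for i in range(n_runs):
            r = np.random.default_rng(700 + i)
            n = 40
            base = r.poisson(4.0 * np.exp(0.9 * r.standard_normal(n) - 0.405))
            conds = [r.poisson(10.0, n).astype(float) for _ in range(4)]
            lab = classify_unit_modulation(conds, base.astype(float), B=3000, seed=i)
            amps += lab.unit_class == "amplifier"
        # 4 conditions at the 5% flag level -> ~18% chance of any false increase
        assert amps / n_runs <= 0.3

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            classify_unit_modulation([np.arange(5.0)], np.array([1.0]))


class TestMeanMatching:
    def test_identical_histograms_keep_everything(self, rng):
        pts = rng.poisson(6, size=(30, 50)).astype(float)
        from lamvar.variability import _ff

        raw = float(np.mean(_ff(pts, axis=1)))
        out = mean_matched_fano([pts, pts.copy()], n_reps=5, seed=0)
        assert out[0] == pytest.approx(raw)
        assert out[1] == pytest.approx(raw)

    def test_two_poisson_conditions_matched_ff_near_one(self, rng):
        a = np.stack([rng.poisson(m, 150) for m in rng.uniform(3, 10, 120)])
        b = np.stack([rng.poisson(m, 150) for m in rng.uniform(6, 14, 120)])
        out, hists = mean_matched_fano([a.astype(float), b.astype(float)],
                                       n_reps=20, seed=1, return_histograms=True)
        assert abs(out[0] - 1.0) <= 0.1
        assert abs(out[1] - 1.0) <= 0.1
        for rep in hists:
            assert np.array_equal(rep[0], rep[1])

    def test_gain_modulated_stays_elevated_after_matching(self, rng):
        sig = 0.5
        means = rng.uniform(5, 10, 100)
        gain = np.exp(sig * rng.standard_normal((100, 200)) - sig**2 / 2)
        gm = rng.poisson(means[:, None] * gain)
        po = np.stack([rng.poisson(m, 200) for m in means])
        out = mean_matched_fano([gm.astype(float), po.astype(float)], n_reps=10,
                                seed=2)
        assert out[0] > out[1] + 0.5

    def test_disjoint_conditions_fail_loudly(self, rng):
        a = np.stack([rng.poisson(2, 50) for _ in range(20)])
        b = np.stack([rng.poisson(40, 50) for _ in range(20)])
        with pytest.raises(ValueError, match="common"):
            mean_matched_fano([a.astype(float), b.astype(float)], n_reps=3, seed=0)


class TestMadOutliers:
    def test_obvious_outlier_removed(self):
        out = remove_outliers_mad([1.0, 1.0, 1.1, 0.9, 100.0])
        assert 100.0 not in out
        assert out.size == 4

    def test_clean_data_unchanged(self, rng):
        x = rng.standard_normal(50) * 0.1
        assert remove_outliers_mad(x, k=25.0).size == x.size

    def test_matches_brute_force(self):
        for i in range(200):
            r = np.random.default_rng(i)
            x = r.standard_normal(r.integers(5, 40)) * r.uniform(0.5, 5)
            med = np.median(x)
            mad = np.median(np.abs(x - med))
            if mad == 0:
                continue
            expected = x[np.abs(x - med) / mad < 2.5]
            assert np.array_equal(remove_outliers_mad(x), expected)

    def test_zero_mad_keeps_all_with_warning(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="MAD"):
            out = remove_outliers_mad(x)
        assert out.size == x.size
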