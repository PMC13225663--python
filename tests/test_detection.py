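import numpy as np
import pytest

from placecells import (NullDistribution, binned_proportion_curve,
                        circular_surrogates, classify_cells,
                        null_distributions, permutation_test,
                        rate_row_surrogates)
from placecells.detection import apply_circular_shift


@pytest.fixture
def spike_train():
    rng = np.random.default_rng(0)
    return np.sort(rng.uniform(0, 100, size=250))


class TestCircularSurrogates:
    def test_zero_offset_is_identity(self, spike_train):
        out = apply_circular_shift(spike_train, (0, 100), 0.0)
        np.testing.assert_allclose(out, spike_train)

    def test_full_period_offset_is_identity(self, spike_train):
        out = apply_circular_shift(spike_train, (0, 100), 100.0)
        np.testing.assert_allclose(out, spike_train, atol=1e-9)

    def test_spike_count_and_bounds_preserved(self, spike_train):
        surr = circular_surrogates(spike_train, (0, 100), n=50, seed=1)
        assert surr.shape == (50, spike_train.size)
        assert np.all((surr >= 0) & (surr <= 100))
        assert np.all(np.diff(surr, axis=1) >= 0)

    def test_circular_gap_multiset_preserved(self, spike_train):
        """Treating the session as a circle, the multiset of gaps between
        consecutive spikes (including the wrap gap) is invariant."""
        def circular_gaps(train, T=100.0):
            gaps = np.diff(train)
            wrap = T - train[-1] + train[0]
            return np.sort(np.append(gaps, wrap))

        surr = circular_surrogates(spike_train, (0, 100), n=20, seed=2)
        base = circular_gaps(spike_train)
        for s in surr:
            np.testing.assert_allclose(circular_gaps(s), base, atol=1e-8)

    def test_min_shift_respected(self, spike_train):
        surr = circular_surrogates(spike_train, (0, 100), n=200, seed=3,
                                   min_shift_s=5.0)
        # a shift of >= 5 s moves the first spike away from its original slot
        assert not np.any(np.all(np.isclose(surr, spike_train), axis=1))

    def test_short_session_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            circular_surrogates(np.array([0.5]), (0, 1.5), n=5, seed=0,
                                min_shift_s=1.0)


class TestRateRowSurrogates:
    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="at least 2 bins"):
            rate_row_surrogates(np.ones((5, 1)), n=3, seed=0)

    def test_flat_matrix_surrogates_identical(self):
        m = np.full((4, 10), 3.0)
        surr = rate_row_surrogates(m, n=5, seed=0)
        for s in surr:
            np.testing.assert_array_equal(s, m)

    def test_row_sums_and_multisets_preserved(self):
        m = np.random.default_rng(1).uniform(0, 10, size=(8, 15))
        surr = rate_row_surrogates(m, n=30, seed=2)
        np.testing.assert_allclose(surr.sum(axis=2),
                                   np.tile(m.sum(axis=1), (30, 1)))
        for s in surr:
            np.testing.assert_allclose(np.sort(s, axis=1), np.sort(m, axis=1))

    def test_seed_reproducibility(self, noisy_matrix):
        a = rate_row_surrogates(noisy_matrix, n=10, seed=9)
        b = rate_row_surrogates(noisy_matrix, n=10, seed=9)
        np.testing.assert_array_equal(a, b)
        si_a, f_a = null_distributions(noisy_matrix, n=50, seed=4)
        si_b, f_b = null_distributions(noisy_matrix, n=50, seed=4)
        np.testing.assert_array_equal(si_a.values, si_b.values)
        np.testing.assert_array_equal(f_a.values, f_b.values)


class TestPermutationTest:
    def null(self):
        return NullDistribution(np.arange(1000, dtype=float),
                                "rate_row_shift")

    def test_observed_above_all_nulls(self):
        p, sig = permutation_test(2000.0, self.null())
        assert p == pytest.approx(1 / 1001)
        assert sig

    def test_observed_at_median(self):
        p, sig = permutation_test(499.5, self.null())
        assert p == pytest.approx(0.5, abs=0.01)
        assert not sig

    def test_observed_below_all_nulls(self):
        p, sig = permutation_test(-1.0, self.null())
        assert p == 1.0 and not sig

    def test_tie_at_percentile_not_significant(self):
        null = NullDistribution(np.full(100, 5.0), "rate_row_shift")
        _, sig = permutation_test(5.0, null)
        assert not sig  # strict exceedance required

    def test_nan_observed_not_significant(self):
        p, sig = permutation_test(float("nan"), self.null())
        assert np.isnan(p) and not sig


class TestClassification:
    def test_four_way_partition(self):
        si = np.array([True, True, False, False])
        f = np.array([True, False, True, False])
        cats, counts = classify_cells(si, f)
        assert cats.tolist() == ["both", "si_only", "anova_only", "neither"]
        assert sum(counts.values()) == 4

    def test_threshold_mode_example(self):
        # SI = 0.3 exceeds the 0.25 threshold; ANOVA not significant
        sig_si_thresh = np.array([0.3 > 0.25])
        cats, _ = classify_cells(sig_si_thresh, np.array([False]))
        assert cats[0] == "si_only"

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        si, f = rng.random(100) < 0.6, rng.random(100) < 0.7
        _, counts = classify_cells(si, f)
        props = {k: v / 100 for k, v in counts.items()}
        assert sum(props.values()) == pytest.approx(1.0)

    def test_missing_flags_rejected(self):
        with pytest.raises(ValueError, match="boolean"):
            classify_cells(np.array([1.0, np.nan]), np.array([1.0, 0.0]))


class TestThresholdFragility:
    def test_fixed_si_threshold_less_stable_than_permutation(self):
        """Re-binning the same population moves the fraction above the fixed
        SI cutoff far more than the permutation-significant fraction."""
        from dataclasses import replace

        from placecells import (Geometry, SweepSpec, rebin, sample_population,
                                spatial_information)
        from placecells.simulate import DEFAULT_SWEEP_FIXED

        fixed = replace(DEFAULT_SWEEP_FIXED, mu=29.5, a=4.0)
        spec = SweepSpec("width", 2, 10, 120, fixed=fixed, n_trials=20,
                         seed=77)
        population = sample_population(spec, geometry=Geometry.linear(60))
        thresh_fracs, perm_fracs = [], []
        for n_bins in (10, 20, 30):
            above, sig = [], []
            for i, (_, m) in enumerate(population):
                coarse = rebin(m, n_bins)
                si = spatial_information(coarse.mean_map())
                si_null, _ = null_distributions(
                    coarse, n=300, seed=np.random.SeedSequence((5, i, n_bins)))
                above.append(si > 0.25)
                sig.append(permutation_test(si, si_null)[1])
            thresh_fracs.append(np.mean(above))
            perm_fracs.append(np.mean(sig))
        thresh_change = max(thresh_fracs) / min(thresh_fracs)
        perm_change = max(perm_fracs) / max(min(perm_fracs), 1e-9)
        assert thresh_change > 1.5
        assert perm_change < thresh_change


class TestProportionCurve:
    def test_all_true_is_one_everywhere(self):
        scores = np.linspace(0, 1, 100)
        _, props = binned_proportion_curve(scores, np.ones(100, bool), 10)
        np.testing.assert_array_equal(props, np.ones(10))

    def test_indicator_flags_form_a_step(self):
        scores = np.linspace(0, 1, 200)
        flags = scores > 0.5
        centers, props = binned_proportion_curve(scores, flags, 10)
        assert np.all(np.diff(props) >= 0)
        assert props[0] == 0.0 and props[-1] == 1.0
        assert np.all(np.diff(centers) > 0)

    def test_self_agreement_is_one(self):
        rng = np.random.default_rng(4)
        scores = rng.random(100)
        flags = rng.random(100) < 0.5
        _, props = binned_proportion_curve(scores, flags == flags, 5)
        np.testing.assert_array_equal(props, np.ones(5))

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError, match="fewer neurons"):
            binned_proportion_curve(np.arange(5.0), np.ones(5, bool), 10)
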