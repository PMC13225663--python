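import numpy as np
import pytest
from scipy import stats

from placecells import (Geometry, PositionTrace, QCCriteria, TrialRateMatrix,
                        compute_occupancy, qc_filter, rebin, smooth_map,
                        synthesize_spikes, trial_rate_matrix)
from placecells.ratemaps import (NeuronSummary, SessionSummary,
                                 mask_edge_bins, valid_trials)


def uniform_trace(n_bins=50, samples_per_bin=20, dt=0.1):
    n = n_bins * samples_per_bin
    times = np.arange(n) * dt
    positions = (np.arange(n) + 0.5) / n * n_bins
    return PositionTrace(times, positions)


class TestOccupancy:
    def test_uniform_traversal(self, geom50):
        occ = compute_occupancy(uniform_trace(), geom50)
        np.testing.assert_allclose(occ.p_x, np.full(50, 0.02))
        assert occ.p_x.sum() == pytest.approx(1.0, abs=1e-12)

    def test_speed_filter_excludes_slow_samples(self, geom50):
        trace = uniform_trace()
        speed = np.where(np.arange(trace.times.size) % 2 == 0, 0.0, 10.0)
        trace = PositionTrace(trace.times, trace.positions, speed=speed)
        occ_all = compute_occupancy(trace, geom50, min_speed=0.0)
        occ_fast = compute_occupancy(trace, geom50, min_speed=5.0)
        assert occ_fast.seconds_per_bin.sum() == pytest.approx(
            occ_all.seconds_per_bin.sum() / 2, rel=0.02)

    def test_all_filtered_is_error(self, geom50):
        trace = uniform_trace()
        trace = PositionTrace(trace.times, trace.positions,
                              speed=np.zeros_like(trace.times))
        with pytest.raises(ValueError, match="empty occupancy"):
            compute_occupancy(trace, geom50, min_speed=5.0)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_probability_normalisation(self, geom50, seed):
        rng = np.random.default_rng(seed)
        times = np.cumsum(rng.uniform(0.01, 0.2, size=500))
        positions = rng.uniform(0, 50, size=500)
        occ = compute_occupancy(PositionTrace(times, positions), geom50)
        assert occ.p_x.sum() == pytest.approx(1.0, abs=1e-12)


class TestTrialRateMatrix:
    def test_rate_definition(self):
        geom = Geometry.linear(5)
        trace = uniform_trace(n_bins=5, samples_per_bin=15, dt=0.1)
        # each bin occupied exactly 1.5 s; 3 spikes while in bin 2
        bin2_times = trace.times[(trace.positions >= 2) & (trace.positions < 3)]
        spikes = bin2_times[[2, 7, 12]]
        windows = np.array([[0.0, trace.times[-1] + 0.1]])
        matrix, occ = trial_rate_matrix(spikes, trace, geom, windows)
        assert occ[0, 2] == pytest.approx(1.5)
        assert matrix.rates[0, 2] == pytest.approx(2.0)

    def test_no_spikes_gives_zero_row(self, geom50):
        trace = uniform_trace()
        windows = np.array([[0.0, trace.times[-1] + 0.1]])
        matrix, occ = trial_rate_matrix(np.array([]), trace, geom50, windows)
        occupied = occ[0] > 0
        assert np.all(matrix.rates[0, occupied] == 0.0)

    def test_round_trip_recovers_constant_rate(self):
        """Spikes synthesized at 10 Hz come back as ~10 Hz rate maps."""
        rates = np.full((10, 20), 10.0)
        spikes, pos, windows = synthesize_spikes(rates, 10.0, seed=7)
        trace = PositionTrace(pos["time_s"], pos["position"])
        matrix, occ = trial_rate_matrix(spikes, trace, Geometry.linear(20),
                                        windows)
        total_time = occ.sum()
        lo, hi = stats.poisson.interval(0.99, 10.0 * total_time)
        total_spikes = np.nansum(matrix.rates * occ)
        assert lo <= total_spikes <= hi
        assert np.nanmean(matrix.rates) == pytest.approx(10.0, rel=0.1)

    def test_rate_occupancy_conservation_identity(self):
        """sum_bins rate * seconds equals each trial's spike count exactly."""
        rng = np.random.default_rng(11)
        rates = rng.uniform(0, 15, size=(6, 25))
        spikes, pos, windows = synthesize_spikes(rates, 12.0, seed=8)
        trace = PositionTrace(pos["time_s"], pos["position"])
        matrix, occ = trial_rate_matrix(spikes, trace, Geometry.linear(25),
                                        windows)
        for t, (t0, t1) in enumerate(windows):
            n_spikes = np.sum((spikes >= t0) & (spikes < t1))
            recovered = np.nansum(matrix.rates[t] * occ[t])
            assert recovered == pytest.approx(n_spikes, abs=1e-9)

    def test_binning_refinement_conserves_counts(self):
        rates = np.full((4, 10), 8.0)
        spikes, pos, windows = synthesize_spikes(rates, 10.0, seed=9)
        trace = PositionTrace(pos["time_s"], pos["position"])
        totals = []
        for n_bins in (10, 20):
            geom = Geometry.linear(n_bins, bin_width=10 / n_bins)
            matrix, occ = trial_rate_matrix(spikes, trace, geom, windows)
            totals.append(np.nansum(matrix.rates * occ, axis=1))
        np.testing.assert_allclose(totals[0], totals[1], atol=1e-9)

    def test_overlapping_windows_rejected(self, geom50):
        trace = uniform_trace()
        with pytest.raises(ValueError, match="overlap"):
            trial_rate_matrix(np.array([1.0]), trace, geom50,
                              np.array([[0.0, 5.0], [4.0, 8.0]]))


class TestSmoothing:
    def test_zero_kernel_is_identity(self, noisy_matrix):
        out = smooth_map(noisy_matrix.rates, 0.0)
        np.testing.assert_array_equal(out, noisy_matrix.rates)

    @pytest.mark.parametrize("sd", [0.5, 1.0, 3.0])
    def test_flat_map_invariant(self, sd):
        flat = np.full(40, 2.5)
        np.testing.assert_allclose(smooth_map(flat, sd), flat, rtol=1e-12)

    def test_interior_mass_is_conserved(self, geom50):
        """With the field supported away from the edges, smoothing preserves
        each row's mean to numerical precision."""
        x = np.arange(50.0)
        row = 10 * np.exp(-((x - 25) ** 2) / 18)
        m = np.tile(row, (3, 1))
        out = smooth_map(m, 1.0)
        np.testing.assert_allclose(out.mean(axis=1), m.mean(axis=1),
                                   rtol=1e-9)

    def test_nan_bins_survive(self):
        row = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        out = smooth_map(row, 1.0)
        assert np.isnan(out[2]) and not np.any(np.isnan(np.delete(out, 2)))

    def test_2d_smoothing_spreads_over_the_grid(self, grid10):
        row = np.zeros(100)
        row[44] = 10.0  # grid cell (4, 4)
        out = smooth_map(row, 1.0, grid10).reshape(10, 10)
        assert out[4, 4] < 10.0
        assert out[5, 4] > 0 and out[4, 5] > 0
        assert out[5, 4] == pytest.approx(out[3, 4], rel=1e-9)


class TestQC:
    def good_session(self):
        return SessionSummary(np.full(20, 10.0))

    def test_low_rate_dropped(self):
        keep, rules = qc_filter(NeuronSummary(0.1, 200, 0.9),
                                self.good_session())
        assert not keep and rules == ["min_rate"]

    def test_too_few_trials_dropped(self):
        keep, rules = qc_filter(NeuronSummary(1.0, 200, 0.9),
                                SessionSummary(np.full(14, 10.0)))
        assert not keep and rules == ["min_trials"]

    def test_good_neuron_kept(self):
        keep, rules = qc_filter(NeuronSummary(1.0, 60, 0.8),
                                self.good_session())
        assert keep and rules == []

    def test_multiple_violations_all_named(self):
        keep, rules = qc_filter(NeuronSummary(25.0, 10, 0.1),
                                self.good_session())
        assert not keep
        assert set(rules) == {"max_rate", "min_spikes", "min_presence"}

    def test_duration_outliers_reduce_trial_count(self):
        durations = np.concatenate([np.full(15, 10.0), [40.0]])
        mask = valid_trials(SessionSummary(durations), 2.0)
        assert mask.sum() == 15 and not mask[-1]
        keep, rules = qc_filter(NeuronSummary(1.0, 60, 0.8),
                                SessionSummary(durations))
        assert keep  # 15 clean trials remain, exactly at the floor


class TestRebinAndMask:
    def test_rebin_conserves_trial_means(self, noisy_matrix):
        coarse = rebin(noisy_matrix, 10)
        np.testing.assert_allclose(coarse.rates.mean(axis=1),
                                   noisy_matrix.rates.mean(axis=1), rtol=1e-12)
        assert coarse.geometry.shape == (10,)

    def test_non_divisor_rejected(self, noisy_matrix):
        with pytest.raises(ValueError, match="does not divide"):
            rebin(noisy_matrix, 7)

    def test_2d_rebin(self, grid10):
        m = TrialRateMatrix(np.arange(300, dtype=float).reshape(3, 100),
                            grid10)
        coarse = rebin(m, (5, 5))
        assert coarse.rates.shape == (3, 25)
        np.testing.assert_allclose(coarse.rates.mean(axis=1),
                                   m.rates.mean(axis=1), rtol=1e-12)

    def test_edge_mask(self, noisy_matrix):
        masked = mask_edge_bins(noisy_matrix, 3)
        assert np.all(np.isnan(masked.rates[:, :3]))
        assert np.all(np.isnan(masked.rates[:, -3:]))
        assert not np.any(np.isnan(masked.rates[:, 3:-3]))
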