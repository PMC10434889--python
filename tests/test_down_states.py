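import numpy as np
import pytest

import sleepdyn as sd
from sleepdyn.core import PopulationTrajectory
from sleepdyn.down_states import DownStateSeries, interval_precision_recall


def _merged_spikes(times):
    return sd.SpikeTrainSet(
        neuron_ids=["a"],
        spike_times={"a": np.asarray(times, dtype=float)},
        t_start=0.0,
        t_end=float(times[-1]) + 0.01,
    )


def _traj(counts):
    counts = np.asarray(counts)
    return PopulationTrajectory(
        counts=counts,
        bin_width=0.05,
        bin_starts=0.05 * np.arange(counts.shape[0]),
        neuron_ids=[f"n{i}" for i in range(counts.shape[1])],
    )


class TestOffDetection:
    def test_dense_firing_has_no_off(self):
        spikes = _merged_spikes(np.arange(0, 2, 0.02))
        assert len(sd.detect_off_periods(spikes)) == 0

    def test_hand_gaps_against_both_bounds(self):
        spikes = _merged_spikes([0.0, 0.04, 0.12, 1.50])
        off = sd.detect_off_periods(spikes)
        assert off.intervals == [(0.04, 0.12)]

    def test_empty_spike_set_errors(self):
        empty = sd.SpikeTrainSet(neuron_ids=[], spike_times={}, t_start=0, t_end=1)
        with pytest.raises(ValueError):
            sd.detect_off_periods(empty)

    def test_off_intervals_contain_no_spikes(self, standard_session):
        spikes, hyp, _ = standard_session
        sws = sd.restrict_to_state(spikes, hyp, "SWS")
        merged = sws.merged()
        off = sd.detect_off_periods(sws)
        for a, b in off.intervals:
            inside = np.count_nonzero((merged > a) & (merged < b))
            assert inside == 0

    def test_planted_interval_recovery(self, standard_session):
        """Neocortex-like sessions: detected OFF matches planted DOWN."""
        spikes, hyp, truth = standard_session
        sws = sd.restrict_to_state(spikes, hyp, "SWS")
        off = sd.detect_off_periods(sws)
        assert sd.interval_jaccard(off, truth) >= 0.9
        precision, recall = interval_precision_recall(off, truth)
        assert precision >= 0.95 and recall >= 0.95


class TestOnDetection:
    def test_count_and_duration_criteria(self):
        # OFF at [1.0,1.1] and [1.4,1.5]; segment between has 12 spikes, 300 ms
        times = np.concatenate([
            [0.5, 1.0], np.linspace(1.1, 1.4, 12), [1.5, 2.0],
        ])
        spikes = _merged_spikes(np.unique(times))
        off = sd.IntervalSet([(1.0, 1.1), (1.4, 1.5)], label="OFF")
        on = sd.detect_on_periods(spikes, off)
        assert on.intervals == [(1.1, 1.4)]

    def test_too_few_spikes_rejected(self):
        times = np.concatenate([[0.5, 1.0], np.linspace(1.1, 1.4, 5), [1.5, 2.0]])
        spikes = _merged_spikes(np.unique(times))
        off = sd.IntervalSet([(1.0, 1.1), (1.4, 1.5)], label="OFF")
        assert len(sd.detect_on_periods(spikes, off)) == 0

    def test_too_long_segment_rejected(self):
        times = np.concatenate([[0.0, 0.5], np.linspace(0.6, 5.5, 500), [5.6, 6.0]])
        spikes = _merged_spikes(np.unique(times))
        off = sd.IntervalSet([(0.5, 0.6), (5.5, 5.6)], label="OFF")
        assert len(sd.detect_on_periods(spikes, off)) == 0


class TestFractionRule:
    def test_all_active_never_down(self):
        traj = _traj(np.ones((10, 20), dtype=int))
        assert sd.detect_fraction_down(traj).is_down.sum() == 0

    def test_five_percent_is_down(self):
        counts = np.zeros((1, 20), dtype=int)
        counts[0, 0] = 1  # 5% of neurons active
        assert sd.detect_fraction_down(_traj(counts)).is_down[0] == 1

    def test_exact_threshold_is_not_down(self):
        counts = np.zeros((1, 20), dtype=int)
        counts[0, :2] = 1  # exactly 10%: strict "<" keeps the bin UP
        assert sd.detect_fraction_down(_traj(counts)).is_down[0] == 0

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            sd.detect_fraction_down(_traj(np.ones((2, 20), dtype=int)), fraction=1.5)


class TestSeriesConversions:
    def test_interval_series_round_trip_within_one_bin(self):
        traj = _traj(np.ones((100, 12), dtype=int))
        off = sd.IntervalSet([(0.50, 0.85), (2.00, 2.60)], label="OFF")
        series = sd.intervals_to_series(off, traj)
        back = sd.series_to_intervals(series)
        assert len(back) == 2
        for (a, b), (a2, b2) in zip(off.intervals, back.intervals):
            assert abs(a - a2) <= traj.bin_width
            assert abs(b - b2) <= traj.bin_width

    def test_majority_rule_boundary(self):
        traj = _traj(np.ones((4, 12), dtype=int))
        # covers 60% of bin 0 and 20% of bin 1
        off = sd.IntervalSet([(0.00, 0.04)], label="OFF")
        series = sd.intervals_to_series(off, traj)
        np.testing.assert_array_equal(series.is_down, [1, 0, 0, 0])


class TestDownRecurrenceCorrelation:
    def _series(self, bits):
        bits = np.asarray(bits, dtype=np.uint8)
        return DownStateSeries(
            is_down=bits, bin_starts=0.05 * np.arange(bits.size), bin_width=0.05
        )

    def test_perfect_separation(self):
        down = self._series([1, 1, 0, 0])
        r, p = sd.correlate_down_recurrence(down, np.array([10, 10, 0, 0]))
        assert r == pytest.approx(1.0)

    def test_point_biserial_closed_form(self):
        down = self._series([1, 1, 0, 0])
        r, _ = sd.correlate_down_recurrence(down, np.array([5, 3, 1, 1]))
        # pearson of the 0/1 indicator with the profile: 0.75 / (0.5 * sqrt(2.75))
        assert r == pytest.approx(0.75 / (0.5 * np.sqrt(2.75)))

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            sd.correlate_down_recurrence(self._series([1, 1, 1]), np.array([1, 2, 3]))
        with pytest.raises(ValueError):
            sd.correlate_down_recurrence(self._series([1, 0, 1]), np.array([2, 2, 2]))

    def test_down_drives_recurrences_in_synthetic_sws(self, standard_session):
        """DOWN-state bins align with the recurrence-count profile."""
        spikes, hyp, _ = standard_session
        a, b = hyp.epochs("SWS")[0]
        sws = sd.restrict_to_state(spikes, hyp, "SWS")
        traj = sd.bin_population(sws, 0.05, window=(a, a + 100.0))
        eps = sd.wake_epsilon(spikes, hyp)
        rp = sd.recurrence_matrix(traj, eps)
        profile = sd.recurrence_time_profile(rp)
        off = sd.detect_off_periods(sws)
        series = sd.intervals_to_series(off, traj)
        r, p = sd.correlate_down_recurrence(series, profile)
        assert r > 0.5
        assert p < 1e-10


class TestExcludeDownBins:
    def test_identity_without_down(self):
        traj = _traj(np.ones((10, 12), dtype=int))
        series = DownStateSeries(
            is_down=np.zeros(10, dtype=np.uint8),
            bin_starts=traj.bin_starts, bin_width=0.05,
        )
        out = sd.exclude_down_bins(traj, series)
        np.testing.assert_array_equal(out.counts, traj.counts)

    def test_bin_count_reduction(self):
        traj = _traj(np.ones((200, 12), dtype=int))
        bits = np.zeros(200, dtype=np.uint8)
        bits[:50] = 1
        series = DownStateSeries(
            is_down=bits, bin_starts=traj.bin_starts, bin_width=0.05
        )
        assert sd.exclude_down_bins(traj, series).n_bins == 150

    def test_all_down_errors(self):
        traj = _traj(np.ones((5, 12), dtype=int))
        series = DownStateSeries(
            is_down=np.ones(5, dtype=np.uint8),
            bin_starts=traj.bin_starts, bin_width=0.05,
        )
        with pytest.raises(ValueError):
            sd.exclude_down_bins(traj, series)
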