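import numpy as np
import pytest

import sleepdyn as sd
from sleepdyn.core import PopulationTrajectory
from sleepdyn.rqa import summed_count_epsilon

from .oracles import brute_rqa


def _traj(counts, bin_width=0.05):
    counts = np.atleast_2d(np.asarray(counts))
    if counts.shape[0] == 1:
        counts = counts.T
    return PopulationTrajectory(
        counts=counts,
        bin_width=bin_width,
        bin_starts=bin_width * np.arange(counts.shape[0]),
        neuron_ids=[f"n{i}" for i in range(counts.shape[1])],
    )


CHECKER = np.array(
    [[1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1]], dtype=np.uint8
)


class TestWakeEpsilon:
    def _session(self, per_bin_counts):
        # one neuron, per_bin_counts spikes in consecutive 50 ms Wake bins
        times = []
        for i, c in enumerate(per_bin_counts):
            times.extend(0.05 * i + 0.001 * (1 + np.arange(c)))
        spikes = sd.SpikeTrainSet(
            neuron_ids=["a"],
            spike_times={"a": np.array(times)},
            t_start=0.0,
            t_end=0.05 * len(per_bin_counts),
        )
        hyp = sd.Hypnogram([(0.0, 0.05 * len(per_bin_counts), "Wake")])
        return spikes, hyp

    def test_constant_counts_give_zero(self):
        spikes, hyp = self._session([7] * 8)
        assert sd.wake_epsilon(spikes, hyp) == 0.0

    def test_closed_form_sd(self):
        spikes, hyp = self._session([2, 4, 6, 8])
        assert sd.wake_epsilon(spikes, hyp) == pytest.approx(np.sqrt(5.0))

    def test_sd_multiplier_for_robustness_sweep(self):
        spikes, hyp = self._session([2, 4, 6, 8])
        for n_sd in (0.0, 2.0, 4.0):
            assert sd.wake_epsilon(spikes, hyp, n_sd=n_sd) == pytest.approx(
                n_sd * np.sqrt(5.0)
            )

    def test_no_wake_errors(self):
        spikes, hyp = self._session([1, 2])
        bad = sd.Hypnogram([(0.0, 0.1, "SWS")])
        with pytest.raises(ValueError):
            sd.wake_epsilon(spikes, bad)


class TestRecurrenceMatrix:
    def test_constant_trajectory_all_ones(self):
        rp = sd.recurrence_matrix(_traj([3, 3, 3, 3]), epsilon=0.0)
        assert rp.R.all()

    def test_zero_epsilon_exact_patterns(self):
        rp = sd.recurrence_matrix(_traj([[1, 2], [1, 2], [2, 1]]), epsilon=0.0)
        assert rp.R[0, 1] == 1 and rp.R[0, 2] == 0

    def test_hand_computed_checkerboard(self):
        rp = sd.recurrence_matrix(_traj([0, 3, 0, 3]), epsilon=1.0)
        np.testing.assert_array_equal(rp.R, CHECKER)

    def test_nonfinite_rejected(self):
        t = _traj([0.0, 1.0, 2.0])
        t.counts = t.counts.astype(float)
        t.counts[0, 0] = np.nan
        with pytest.raises(ValueError):
            sd.recurrence_matrix(t, epsilon=1.0)


class TestRQAMetrics:
    def test_fully_recurrent_limit(self):
        rp = sd.RecurrencePlot(R=np.ones((200, 200), dtype=np.uint8), epsilon=1.0)
        m = sd.rqa_metrics(rp)
        assert m.rr == 1.0
        # the two off-identity corner diagonals have length 1, so DET is a
        # hair below 1: 39798/39800 by direct line enumeration
        assert m.det == pytest.approx(39798 / 39800)
        assert m.lam == 1.0
        assert m.tt == 200.0
        assert m.div == pytest.approx(1 / 199)

    def test_checkerboard_line_structure(self):
        m = sd.rqa_metrics(sd.RecurrencePlot(R=CHECKER, epsilon=1.0))
        assert m.rr == 0.5
        assert m.det == 1.0
        assert m.lam == 0.0
        assert m.tt == 0.0
        assert m.div == 0.5

    def test_identity_only_plot(self):
        m = sd.rqa_metrics(sd.RecurrencePlot(R=np.eye(6, dtype=np.uint8), epsilon=0.0))
        assert m.det == 0.0 and m.lam == 0.0 and m.tt == 0.0 and m.div == 1.0

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(10):
            R = (rng.random((30, 30)) < 0.2).astype(np.uint8)
            R = np.triu(R) | np.triu(R).T
            np.fill_diagonal(R, 1)
            fast = sd.rqa_metrics(sd.RecurrencePlot(R=R, epsilon=1.0)).as_dict()
            slow = brute_rqa(R)
            for k in fast:
                assert fast[k] == pytest.approx(slow[k], abs=1e-12), k


class TestRecurrenceProfile:
    @pytest.mark.parametrize(
        "R, expected",
        [
            (np.ones((4, 4), dtype=np.uint8), [4, 4, 4, 4]),
            (np.eye(4, dtype=np.uint8), [1, 1, 1, 1]),
            (CHECKER, [2, 2, 2, 2]),
        ],
    )
    def test_column_sums(self, R, expected):
        prof = sd.recurrence_time_profile(sd.RecurrencePlot(R=R, epsilon=1.0))
        np.testing.assert_array_equal(prof, expected)


class TestWindowedRQA:
    def test_window_count_and_consistency(self, rng):
        counts = rng.poisson(2.0, size=(600, 10))
        traj = _traj(counts)
        ms = sd.windowed_rqa(traj, epsilon=3.0, window_len=10.0)
        assert len(ms) == 3
        sub = _traj(counts[200:400])
        standalone = sd.rqa_metrics(sd.recurrence_matrix(sub, 3.0))
        assert ms[1].as_dict() == standalone.as_dict()

    def test_too_short_returns_empty_with_warning(self, rng):
        traj = _traj(rng.poisson(2.0, size=(100, 5)))
        with pytest.warns(UserWarning):
            assert sd.windowed_rqa(traj, 1.0, window_len=10.0) == []

    def test_sws_windows_more_recurrent_than_wake(self, standard_session):
        spikes, hyp, _ = standard_session
        eps = sd.wake_epsilon(spikes, hyp)
        from sleepdyn.pipeline import session_state_metrics

        wake = session_state_metrics(spikes, hyp, "Wake", eps)
        sws = session_state_metrics(spikes, hyp, "SWS", eps)
        assert sws["RR"] > wake["RR"]


class TestInvariants:
    def test_rr_monotone_in_epsilon(self, rng):
        traj = _traj(rng.poisson(3.0, size=(100, 8)))
        rrs = [
            sd.rqa_metrics(sd.recurrence_matrix(traj, e)).rr
            for e in np.linspace(0, 8, 9)
        ]
        assert all(b >= a for a, b in zip(rrs, rrs[1:]))

    def test_neuron_permutation_invariance(self, rng):
        counts = rng.poisson(3.0, size=(80, 12))
        perm = rng.permutation(12)
        m1 = sd.rqa_metrics(sd.recurrence_matrix(_traj(counts), 4.0)).as_dict()
        m2 = sd.rqa_metrics(sd.recurrence_matrix(_traj(counts[:, perm]), 4.0)).as_dict()
        assert m1 == m2

    def test_metric_bounds(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            traj = _traj(r.poisson(2.0, size=(60, 6)))
            m = sd.rqa_metrics(sd.recurrence_matrix(traj, 2.0))
            assert 0 <= m.det <= 1 and 0 <= m.lam <= 1
            assert 0 < m.div <= 1
            assert (m.tt == 0) == (not any(v >= 2 for v in m.vertical_hist))

    def test_model_epsilon_matches_summed_sd(self, rng):
        traj = _traj(rng.poisson(2.0, size=(100, 6)))
        assert summed_count_epsilon(traj) == pytest.approx(
            traj.counts.sum(axis=1).std()
        )
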