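"""HMM idealization, transition density plots and kinetic statistics."""

import numpy as np
import pytest

from slidefret import (FretHmm, FretTrace, StateModel, build_tdp, emit_fret,
                       fit_hmm, idealize, recognition_efficiency,
                       simulate_state_traces, transition_stats)
from slidefret.hmm_tdp import (Idealization, TransitionStats,
                               merge_short_dwells, segments_from_path)
from slidefret.state_sim import dominant_state_path


def alternating_trace(levels=(0.1, 0.9), block=20, n_blocks=10):
    e = np.concatenate([np.full(block, levels[i % len(levels)])
                        for i in range(n_blocks)])
    return FretTrace({"efret1": e})


class TestFitHmm:
    def test_noiseless_two_level_means(self):
        hmm = fit_hmm([alternating_trace()], n_states=2, seed=0)
        assert np.allclose(hmm.means_, [0.1, 0.9], atol=1e-3)

    def test_single_state_mean_is_trace_mean(self):
        rng = np.random.default_rng(1)
        tr = FretTrace({"efret1": rng.normal(0.5, 0.05, 500)})
        hmm = fit_hmm([tr], n_states=1, seed=0)
        assert hmm.means_[0] == pytest.approx(
            float(np.mean(tr.efficiencies["efret1"])), abs=1e-6)

    def test_loglik_monotone(self):
        model = StateModel(seed=2)
        traces, _ = simulate_state_traces(model, 10, 1000, seed=2)
        hmm = fit_hmm(traces, n_states=3, seed=0)
        ll = hmm.loglik_history_
        assert all(b >= a - 1e-8 for a, b in zip(ll, ll[1:]))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm([FretTrace({"efret1": np.full(20, 0.5)})], n_states=3)


class TestIdealize:
    def test_noiseless_alternating_exact(self):
        tr = alternating_trace()
        hmm = fit_hmm([tr], n_states=2, seed=0)
        ideal = idealize(hmm, tr)
        expected = np.concatenate([np.full(20, i % 2) for i in range(10)])
        assert np.array_equal(ideal.states, expected)

    def test_single_state_single_segment(self):
        rng = np.random.default_rng(3)
        tr = FretTrace({"efret1": rng.normal(0.5, 0.02, 300)})
        hmm = fit_hmm([tr], n_states=1, seed=0)
        ideal = idealize(hmm, tr)
        assert len(ideal.segments) == 1

    def test_framewise_accuracy_on_noisy_traces(self, state_run):
        accs = []
        for dwells, trace, ideal in zip(state_run["truths"][:50],
                                        state_run["traces"][:50],
                                        state_run["ideals"][:50]):
            truth = dominant_state_path(dwells, 0.03, trace.n_frames)
            accs.append(np.mean(truth == ideal.states))
        assert np.mean(accs) > 0.98

    def test_merge_short_dwells(self):
        path = np.array([0] * 10 + [1] + [2] * 10 + [1] * 3 + [0] * 10)
        merged = merge_short_dwells(path, 2)
        segs = segments_from_path(merged)
        assert all(n >= 2 for _, _, n in segs)
        # the one-frame visit is absorbed into the preceding dwell
        assert [s for s, _, _ in segs] == [0, 2, 1, 0]


class TestTdp:
    def test_counts_match_transitions(self, state_run):
        tdp = build_tdp(state_run["ideals"], state_run["hmm"], bins=50)
        n_expected = sum(i.n_transitions for i in state_run["ideals"])
        assert tdp.n_transitions == n_expected
        assert tdp.hist.sum() == n_expected

    def test_three_state_run_populates_six_clusters(self, state_run):
        tdp = build_tdp(state_run["ideals"], state_run["hmm"], bins=10)
        assert (tdp.hist > 0).sum() == 6  # model-mean coordinates: 6 cells

    def test_single_dwell_empty_with_warning(self):
        ideal = Idealization(states=np.zeros(50, dtype=int),
                             segments=[(0, 0, 50)])
        hmm = FretHmm(n_states=1)
        hmm.means_ = np.array([0.5])
        with pytest.warns(UserWarning):
            tdp = build_tdp([ideal], hmm)
        assert tdp.n_transitions == 0

    def test_measured_segment_means_variant(self):
        tr = alternating_trace()
        hmm = fit_hmm([tr], n_states=2, seed=0)
        ideal = idealize(hmm, tr)
        tdp = build_tdp([ideal], hmm, bins=10, traces=[tr])
        assert tdp.n_transitions == 9


class TestTransitionStats:
    def test_direct_rate_ratio(self):
        # 100 s in state 0 with 50 exits to state 1 -> k = 0.5 /s
        path = np.tile(np.concatenate([np.zeros(66), np.ones(10)]), 50)
        ideal = Idealization(states=path.astype(int),
                             segments=segments_from_path(path.astype(int)))
        stats = transition_stats([ideal], 0.03, 2)
        time_in_0 = stats.occupancy[0]
        assert stats.counts[0, 1] / time_in_0 == pytest.approx(
            stats.rates[0, 1])
        assert stats.rates[0, 1] == pytest.approx(50 / time_in_0)

    def test_unvisited_state_rates_absent(self):
        ideal = Idealization(states=np.array([0, 0, 1, 1]),
                             segments=[(0, 0, 2), (1, 2, 2)])
        stats = transition_stats([ideal], 0.03, 3)
        assert np.all(np.isnan(stats.rates[2]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            transition_stats([], 0.03, 3)


class TestRecognitionEfficiency:
    def test_symmetric_counts(self):
        stats = TransitionStats(counts=np.array([[0, 10, 10],
                                                 [5, 0, 0], [5, 0, 0]]),
                                occupancy=np.ones(3), rates=np.zeros((3, 3)))
        assert recognition_efficiency(stats) == 0.5

    def test_direct_formula(self):
        stats = TransitionStats(counts=np.array([[0, 77, 23],
                                                 [0, 0, 0], [0, 0, 0]]),
                                occupancy=np.ones(3), rates=np.zeros((3, 3)))
        assert recognition_efficiency(stats) == pytest.approx(0.77)

    def test_scale_invariance(self):
        c = np.array([[0.0, 11, 9], [3, 0, 2], [4, 1, 0]])
        s1 = TransitionStats(c, np.ones(3), np.zeros((3, 3)))
        s7 = TransitionStats(7 * c, np.ones(3), np.zeros((3, 3)))
        assert recognition_efficiency(s1) == recognition_efficiency(s7)

    def test_zero_denominator_rejected(self):
        stats = TransitionStats(counts=np.zeros((3, 3)),
                                occupancy=np.ones(3), rates=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            recognition_efficiency(stats)
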