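"""Learning steps, memorization tests, curricula, residence times."""

import numpy as np
import pytest

from arpnet import (
    CapacityCurve,
    IOMapping,
    NetworkParams,
    SynapticWeights,
    is_memorized,
    random_state,
    recall_fractions,
    run_curriculum,
    run_learning_step,
    residence_time,
)
from arpnet.protocol import LearningTrace


class TestRunLearningStep:
    def test_pre_engineered_target_succeeds_in_about_t_stab(
        self, engineered_memory
    ):
        p, w, inp, tgt = engineered_memory
        mp = IOMapping(inp, tgt, 0)
        rng = np.random.default_rng(0)
        w2, s2, trace = run_learning_step(
            w, random_state(p, rng), mp, p, T_stab=20.0, T_max=500.0
        )
        assert trace.success
        # relaxation transient plus the stabilization window
        assert trace.duration < 60.0

    def test_plasticity_off_times_out_with_weights_unchanged(self, small_params):
        p = small_params.replace(tau_f=float("inf"), tau_b=float("inf"))
        w = SynapticWeights.zeros(p)
        mp = IOMapping(np.eye(p.N)[0], np.eye(p.N)[1], 0)
        w2, s2, trace = run_learning_step(
            w, random_state(p, np.random.default_rng(1)), mp, p,
            T_stab=5.0, T_max=20.0,
        )
        assert not trace.success
        np.testing.assert_array_equal(w2.J_ih, w.J_ih)
        np.testing.assert_array_equal(w2.J_ho, w.J_ho)
        np.testing.assert_array_equal(w2.J_oh, w.J_oh)

    def test_phase_labels_follow_error_threshold(self, engineered_memory):
        p, w, inp, tgt = engineered_memory
        mp = IOMapping(inp, tgt, 0)
        _, _, trace = run_learning_step(
            w, random_state(p, np.random.default_rng(2)), mp, p,
            T_stab=20.0, T_max=500.0,
        )
        np.testing.assert_array_equal(
            trace.phase_series, (trace.d_series < p.eps_d).astype(int)
        )

    def test_bad_durations_rejected(self, engineered_memory):
        p, w, inp, tgt = engineered_memory
        with pytest.raises(ValueError):
            run_learning_step(
                w, random_state(p, np.random.default_rng(0)),
                IOMapping(inp, tgt, 0), p, T_stab=10.0, T_max=5.0,
            )


class TestMemorization:
    def test_zero_weights_recall_nothing(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        mp = IOMapping(np.eye(p.N)[0], np.eye(p.N)[3], 0)
        mem, frac = is_memorized(w, mp, p, K=10, seed=4)
        assert not mem and frac == 0.0

    def test_engineered_network_recalls(self, engineered_memory):
        p, w, inp, tgt = engineered_memory
        mem, frac = is_memorized(w, IOMapping(inp, tgt, 0), p, K=10, seed=4)
        assert mem and frac == 1.0

    def test_fraction_definition_strictly_above_half(self):
        # memorized iff fraction > 1/2 strictly
        assert (0.6 > 0.5) and not (0.5 > 0.5)

    def test_batched_fractions_match_single_mapping_calls(self, engineered_memory):
        p, w, inp, tgt = engineered_memory
        mps = [IOMapping(inp, tgt, 0), IOMapping(np.eye(p.N)[1], np.eye(p.N)[2], 1)]
        frac = recall_fractions(w, mps, p, K=8, seed=11)
        assert frac.shape == (2,)
        assert frac[0] == 1.0 and frac[1] == 0.0


class TestCapacityCurve:
    def test_count_bound_enforced(self):
        with pytest.raises(ValueError):
            CapacityCurve([2])
        assert CapacityCurve([1, 2, 1]).capacity == 2

    def test_empty_capacity_zero(self):
        assert CapacityCurve([]).capacity == 0


@pytest.fixture(scope="module")
def tiny_run():
    from arpnet import generate_onehot_curriculum

    p = NetworkParams(N=8)
    cur = generate_onehot_curriculum(8, 2, seed=0)
    return p, cur, run_curriculum(p, cur, seed=0, K=10)


class TestRunCurriculum:
    def test_counts_never_exceed_steps(self, tiny_run):
        p, cur, res = tiny_run
        for k, c in enumerate(res.capacity_curve.counts):
            assert 0 <= c <= k + 1

    def test_deterministic_replay(self, tiny_run):
        p, cur, res = tiny_run
        res2 = run_curriculum(p, cur, seed=0, K=10)
        assert res2.capacity_curve.counts == res.capacity_curve.counts
        np.testing.assert_array_equal(
            res2.weight_history[-1].J_ho, res.weight_history[-1].J_ho
        )

    def test_learns_the_first_mapping(self, tiny_run):
        p, cur, res = tiny_run
        assert res.statuses[0] == "success"
        assert res.capacity >= 1

    def test_distinct_ids_required(self, small_params):
        mp = IOMapping(np.eye(6)[0], np.eye(6)[1], 7)
        with pytest.raises(ValueError):
            run_curriculum(small_params, [mp, mp], seed=0)


class TestResidenceTime:
    def _trace(self, times, outputs, phases=None):
        outputs = np.asarray(outputs, dtype=float)
        n = len(times)
        return LearningTrace(
            np.asarray(times, dtype=float),
            np.ones(n),
            np.zeros(n, dtype=int) if phases is None else np.asarray(phases),
            outputs,
            0,
            False,
            float(times[-1]),
        )

    def test_pinned_at_target(self):
        tgt = np.array([0.0, 1.0, 0.0])
        tr = self._trace(np.arange(8.0), np.tile(tgt, (8, 1)))
        stats = residence_time(tr, [tgt])
        assert stats.visited and stats.mean_time == pytest.approx(7.0, abs=1.01)
        assert stats.n_visits == 1

    def test_never_near_any_target(self):
        tgt = np.array([0.0, 1.0, 0.0])
        far = np.tile([1.0, 0.0, 0.0], (5, 1))
        stats = residence_time(self._trace(np.arange(5.0), far), [tgt])
        assert not stats.visited and stats.mean_time == 0.0

    def test_two_visits_mean(self):
        tgt = np.array([1.0, 0.0])
        near, far = [1.0, 0.0], [0.0, 1.0]
        seq = [near, near, far, far, near, near, near, near, far]
        stats = residence_time(self._trace(np.arange(9.0), seq), [tgt])
        assert stats.n_visits == 2
        assert stats.mean_time == pytest.approx((2 + 4) / 2, abs=0.01)

    def test_scaled_by_backward_timescale(self):
        tgt = np.array([1.0, 0.0])
        seq = [[1.0, 0.0]] * 4
        stats = residence_time(self._trace(np.arange(4.0), seq), [tgt], tau_b=10.0)
        assert stats.mean_time == pytest.approx(0.4, abs=0.02)

    def test_search_phase_only_for_learning_traces(self):
        tgt = np.array([1.0, 0.0])
        seq = [[1.0, 0.0]] * 6
        phases = [0, 0, 0, 1, 1, 1]  # second half is stabilization
        stats = residence_time(
            self._trace(np.arange(6.0), seq, phases), [tgt], search_only=True
        )
        assert stats.mean_time == pytest.approx(3.0, abs=0.01)
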