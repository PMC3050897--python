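"""Attractor classification, census, itinerancy, distance profiles."""

import numpy as np
import pytest

from arpnet import (
    IOMapping,
    NetworkParams,
    NetworkState,
    SynapticWeights,
    Trajectory,
    attractor_census,
    find_attractor,
    itinerancy_sequence,
    min_distance_profile,
    overlap,
    random_state,
    simulate,
)
from arpnet.attractors import jacobian_eigenvalues
from conftest import permute_all


class TestOverlap:
    def test_identical_orthogonal_and_diagonal(self):
        t = np.array([1.0, 0.0, 0.0])
        assert overlap(t, t) == pytest.approx(1.0)
        assert overlap(np.array([0.0, 1.0, 0.0]), t) == pytest.approx(0.0)
        assert overlap(np.array([0.5, 0.5, 0.0]), t) == pytest.approx(1 / np.sqrt(2))

    def test_zero_activity_convention(self):
        assert overlap(np.zeros(3), np.array([1.0, 0, 0])) == 0.0


class TestFindAttractor:
    def test_zero_weight_network_fixed_point(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        att = find_attractor(w, None, 0.0, random_state(p, np.random.default_rng(0)), p)
        assert att.kind == "fixed_point"
        # uniform by symmetry
        assert np.ptp(att.representative) < 1e-6

    def test_ring_is_a_limit_cycle_with_reference_period(self, ring_oscillator):
        p, w = ring_oscillator
        st0 = random_state(p, np.random.default_rng(1))
        att = find_attractor(w, None, 0.0, st0, p)
        assert att.kind == "limit_cycle"
        assert att.period is not None and att.period > 0
        # independent long-run check: autocorrelation peak of one output
        trj = simulate(st0, w, None, 0.0, 1000.0, p, record_every=10)
        x = trj.output[len(trj.output) // 2 :, 0]
        x = x - x.mean()
        ac = np.correlate(x, x, mode="full")[x.size - 1 :]
        peak = np.argmax(ac[50:]) + 50  # skip the zero-lag peak
        ref_period = peak * 10 * p.dt
        assert att.period == pytest.approx(ref_period, rel=0.1)

    def test_starting_at_fixed_point_is_idempotent(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        att = find_attractor(w, None, 0.0, random_state(p, np.random.default_rng(2)), p)
        rep = att.representative
        st0 = NetworkState(
            np.clip(rep[: p.N], 1e-9, 1 - 1e-9), np.clip(rep[p.N :], 1e-9, 1 - 1e-9)
        )
        att2 = find_attractor(w, None, 0.0, st0, p, transient=1.0)
        assert att2.kind == "fixed_point"
        np.testing.assert_allclose(att2.representative, rep, atol=1e-5)

    def test_classifier_soundness(self, small_params, ring_oscillator):
        # a relaxing network is never labeled limit_cycle
        p = small_params
        w = SynapticWeights.zeros(p)
        for seed in range(3):
            att = find_attractor(
                w, None, 0.0, random_state(p, np.random.default_rng(seed)), p
            )
            assert att.kind == "fixed_point"
        # a genuinely periodic network is never labeled fixed_point
        pr, wr = ring_oscillator
        for seed in range(3):
            att = find_attractor(
                wr, None, 0.0, random_state(pr, np.random.default_rng(seed)), pr
            )
            assert att.kind == "limit_cycle"

    def test_jacobian_certifies_stability_of_fixed_point(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        att = find_attractor(w, None, 0.0, random_state(p, np.random.default_rng(3)), p)
        eig = jacobian_eigenvalues(att.representative, w, None, 0.0, p)
        assert np.all(eig.real < 0)


class TestCensus:
    def test_zero_weight_census_single_basin(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        atts = attractor_census(w, None, 0.0, p, M=10, seed=0)
        assert len(atts) == 1
        assert atts[0].kind == "fixed_point"
        assert atts[0].basin_count == 10

    def test_census_stable_under_more_samples(self, ring_oscillator):
        p, w = ring_oscillator
        a1 = attractor_census(w, None, 0.0, p, M=5, seed=1)
        a2 = attractor_census(w, None, 0.0, p, M=10, seed=2)
        kinds1 = sorted(a.kind for a in a1)
        kinds2 = sorted(set(a.kind for a in a2))
        assert set(kinds1) == set(kinds2) == {"limit_cycle"}

    def test_census_equivariant_under_relabeling(self, engineered_memory):
        p, w, inp, tgt = engineered_memory
        perm = np.random.default_rng(5).permutation(p.N)
        atts = attractor_census(w, inp, 2.0, p, M=8, seed=3)
        atts_p = attractor_census(
            permute_all(w, perm), inp[perm], 2.0, p, M=8, seed=3
        )
        assert [a.kind for a in atts] == [a.kind for a in atts_p]
        assert [a.basin_count for a in atts] == [a.basin_count for a in atts_p]


class TestItinerancy:
    def _traj(self, outputs, times=None):
        outputs = np.asarray(outputs, dtype=float)
        n = len(outputs)
        times = np.arange(n, dtype=float) if times is None else times
        return Trajectory(times, np.full((n, 2), 0.1), outputs)

    def test_visit_order_recorded(self):
        t1 = np.array([1.0, 0.0, 0.0])
        t2 = np.array([0.0, 1.0, 0.0])
        rest = np.array([0.2, 0.2, 0.2])
        seq = [rest, t1, t1, rest, t2, rest]
        it = itinerancy_sequence(self._traj(seq), [t1, t2])
        assert it.order == [0, 1]
        assert it.distinct_targets() == {0, 1}
        assert it.visits[0].t_entry < it.visits[0].t_exit

    def test_no_visits_empty(self):
        rest = np.array([0.2, 0.2, 0.2])
        it = itinerancy_sequence(self._traj([rest] * 4), [np.eye(3)[0]])
        assert len(it) == 0

    def test_simultaneous_overlap_larger_wins_tie_lower_id(self):
        # activity equally close to two targets -> lower index wins
        t1, t2 = np.eye(3)[0], np.eye(3)[1]
        both = np.array([0.7, 0.7, 0.0])  # overlap 0.7/0.99.. with each
        closer2 = np.array([0.5, 0.9, 0.0])
        it = itinerancy_sequence(self._traj([both, closer2]), [t1, t2],
                                 sim_threshold=0.6)
        assert it.order[0] == 0  # tie at the first sample -> id 0
        assert it.order[-1] == 1


class TestMinDistance:
    def test_initialized_at_reference_gives_zero(self, engineered_memory):
        p, w, inp, tgt = engineered_memory
        mp = IOMapping(inp, tgt, 0)
        from arpnet import evoked_reference_states

        refs, unres = evoked_reference_states(w, [mp], p, seed=0)
        assert not unres
        # spontaneous run seeded exactly at the evoked reference state
        d, _ = min_distance_profile(
            w, [mp], p, n_init=1, seed=0, horizon=1.0, refs=refs
        )
        # the very first tracked sample is the initial state itself only if
        # we start there; instead verify the reference is self-consistent:
        st0 = NetworkState(
            np.clip(refs[0, : p.N], 1e-9, 1 - 1e-9),
            np.clip(refs[0, p.N :], 1e-9, 1 - 1e-9),
        )
        trj = simulate(st0, w, mp.input, p.gamma_learn, 5.0, p)
        final = np.concatenate([trj.hidden[-1], trj.output[-1]])
        assert np.linalg.norm(final - refs[0]) < 1e-5

    def test_nonincreasing_with_longer_horizon(self, small_params, rng):
        p = small_params
        w = SynapticWeights.uniform(p, rng)
        mp = IOMapping(np.eye(p.N)[0], np.eye(p.N)[1], 0)
        d_short, _ = min_distance_profile(w, [mp], p, n_init=20, seed=7,
                                          horizon=5.0, ref_seed=1)
        d_long, _ = min_distance_profile(w, [mp], p, n_init=20, seed=7,
                                         horizon=50.0, ref_seed=1)
        assert d_long[0] <= d_short[0] + 1e-12

    def test_zero_weight_network_symmetric_across_targets(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        mps = [IOMapping(np.eye(p.N)[i], np.eye(p.N)[i], i) for i in range(3)]
        d, _ = min_distance_profile(w, mps, p, n_init=50, seed=3, horizon=30.0,
                                    ref_seed=5)
        # all references coincide with the spontaneous fixed point
        assert np.ptp(d) < 0.05
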