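"""Detection, classification and census of frozen-weight attractors.

After learning, the network with fixed synapses is an autonomous
dynamical system (plus a clamped input, if any).  Its long-run behavior
is classified as a fixed point or a limit cycle; an ensemble of random
initial states yields a census of distinct attractors with basin
counts.  Spontaneous trajectories (no input) are summarized by the
sequence of previously learned targets they approach (itinerancy) and
by the minimum distance their orbit attains to each target's evoked
reference state (the D_min profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dynamics import NetworkState, SynapticWeights, Trajectory, random_state
from .params import NetworkParams
from .patterns import IOMapping

__all__ = [
    "Attractor",
    "ItineraryVisit",
    "ItinerarySequence",
    "overlap",
    "find_attractor",
    "attractor_census",
    "itinerancy_sequence",
    "min_distance_profile",
    "jacobian_eigenvalues",
]


@dataclass
class Attractor:
    """Classified long-run behavior of one trajectory.

    ``kind`` is ``"fixed_point"``, ``"limit_cycle"`` or ``"unresolved"``
    (the trajectory neither converged nor closed on itself within the
    horizon — reported, never silently dropped).  For a fixed point,
    ``representative`` is the state vector (hidden and output rates
    concatenated); for a limit cycle it is one recorded period of such
    vectors (rows).  ``signature`` is the tuple of target indices the
    orbit visits (only set when targets were supplied).
    """

    kind: str
    representative: np.ndarray
    period: float | None = None
    basin_count: int = 1
    signature: tuple[int, ...] = ()
    diagnostics: str = ""

    def output_part(self, params: NetworkParams) -> np.ndarray:
        rep = self.representative
        if rep.ndim == 1:
            return rep[params.N_hid :]
        return rep[:, params.N_hid :]


@dataclass(frozen=True)
class ItineraryVisit:
    target_id: int
    t_entry: float
    t_exit: float


@dataclass
class ItinerarySequence:
    """Ordered visits of a trajectory to previously learned targets."""

    visits: list[ItineraryVisit]

    @property
    def order(self) -> list[int]:
        return [v.target_id for v in self.visits]

    def distinct_targets(self) -> set[int]:
        return {v.target_id for v in self.visits}

    def __len__(self) -> int:
        return len(self.visits)


def overlap(activity: np.ndarray, target: np.ndarray) -> float:
    """Normalized overlap ``O . T / (|O| |T|)`` in [0, 1].

    Zero activity returns 0 by convention (the rest state has no
    preferred direction).
    """
    activity = np.asarray(activity, dtype=float)
    target = np.asarray(target, dtype=float)
    tn = np.linalg.norm(target)
    if tn == 0:
        raise ValueError("target must be nonzero")
    an = np.linalg.norm(activity)
    if an == 0:
        return 0.0
    return float(activity @ target / (an * tn))


def _relax_batch(Xh, Xo, w, I_ext, params, T, conv_tol=0.0):
    """Advance a column batch in place; returns steps run."""
    dummy = np.empty((0, 1, 1))
    steps, _ = _kernels.relax(
        Xh, Xo, w.J_ho, w.J_oh, I_ext, params.c_inh, params.beta,
        params.theta, params.tau, params.dt, int(round(T / params.dt)),
        conv_tol, 0, dummy, dummy,
    )
    return steps


def _record_window(Xh, Xo, w, I_ext, params, T, record_every):
    """Advance while recording; returns (times, states (T, Nh+No, B))."""
    n_steps = int(round(T / params.dt))
    n_frames = n_steps // record_every + 1
    B = Xh.shape[1]
    rec_h = np.empty((n_frames, params.N_hid, B))
    rec_o = np.empty((n_frames, params.N_out, B))
    _, n_rec = _kernels.relax(
        Xh, Xo, w.J_ho, w.J_oh, I_ext, params.c_inh, params.beta,
        params.theta, params.tau, params.dt, n_steps, 0.0, record_every,
        rec_h, rec_o,
    )
    times = params.dt * record_every * np.arange(n_rec)
    states = np.concatenate([rec_h[:n_rec], rec_o[:n_rec]], axis=1)
    return times, states


def _external_drive(w, input, gamma, params, B):
    if input is None:
        return np.zeros((params.N_hid, B))
    xi = np.asarray(input, dtype=float)
    drive = gamma * (w.J_ih @ xi)
    return np.ascontiguousarray(np.repeat(drive[:, None], B, axis=1))


def _classify_cycle(times, orbit, tol_cycle):
    """Period detection by recurrence to a slow reference point.

    The reference is the recorded frame of minimal speed in the second
    half of the window (a dwell plateau of the orbit).  Recurrences are
    the distinct intervals where the normalized distance to the
    reference falls below ``tol_cycle``; a consistent spacing over at
    least three returns is required.

    Returns ``(period, start_idx, end_idx)`` or ``None``.
    """
    n = len(times)
    if n < 8:
        return None
    speed = np.linalg.norm(np.diff(orbit, axis=0), axis=1)
    half = n // 2
    ref_idx = half + int(np.argmin(speed[half:]))
    ref = orbit[ref_idx]
    dist = np.linalg.norm(orbit - ref, axis=1) / np.sqrt(orbit.shape[1])
    if dist.max() < 10 * tol_cycle:
        # the orbit never leaves the reference's neighborhood: not a cycle
        return None
    # returns to the reference = prominent local minima of the distance;
    # tol_cycle is the floor, the threshold adapts to the sampling density
    thr = max(tol_cycle, dist.min() + 0.25 * (np.median(dist) - dist.min()))
    cand = [
        i
        for i in range(1, n - 1)
        if dist[i] <= dist[i - 1] and dist[i] <= dist[i + 1] and dist[i] < thr
    ]
    if len(cand) < 4:
        return None
    gaps = np.diff([times[i] for i in cand])
    period = float(np.median(gaps))
    if period <= 0 or np.max(np.abs(gaps - period)) > 0.2 * period:
        return None
    i0 = cand[-2]
    i1 = cand[-1]
    if i1 <= i0 + 1:
        return None
    return period, i0, i1


def find_attractor(
    w: SynapticWeights,
    input: np.ndarray | None,
    gamma: float,
    state0: NetworkState,
    params: NetworkParams,
    transient: float = 200.0,
    horizon: float = 2000.0,
    tol_fp: float = 1e-6,
    tol_cycle: float = 1e-3,
    targets: list[np.ndarray] | None = None,
    sim_threshold: float = 0.9,
    record_every: int = 25,
) -> Attractor:
    """Classify the attractor reached from one initial state.

    The trajectory is relaxed past ``transient``; if its drift per
    ``tau`` falls below ``tol_fp`` before ``horizon`` it is a fixed
    point.  Otherwise a recording window is scanned for a consistent
    recurrence (at least three returns to within ``tol_cycle``), giving
    a limit cycle with its period; failing both, the result is
    ``unresolved`` with diagnostics.
    """
    w.check_shapes(params)
    Xh = np.ascontiguousarray(state0.x_hidden[:, None].copy())
    Xo = np.ascontiguousarray(state0.x_output[:, None].copy())
    I_ext = _external_drive(w, input, gamma, params, 1)
    _relax_batch(Xh, Xo, w, I_ext, params, transient, conv_tol=0.0)
    # convergence probe: relax with early stop on drift
    steps = _relax_batch(
        Xh, Xo, w, I_ext, params, horizon - transient, conv_tol=tol_fp
    )
    if steps < int(round((horizon - transient) / params.dt)):
        rep = np.concatenate([Xh[:, 0], Xo[:, 0]])
        sig = _visit_signature(rep[None, :], params, targets, sim_threshold)
        return Attractor("fixed_point", rep, None, 1, sig)
    # not converged: record a window and look for recurrences
    window = min(600.0, horizon)
    times, states = _record_window(Xh, Xo, w, I_ext, params, window, record_every)
    orbit = states[:, :, 0]
    hit = _classify_cycle(times, orbit, tol_cycle)
    if hit is not None:
        period, i0, i1 = hit
        rep = orbit[i0:i1]
        sig = _visit_signature(rep, params, targets, sim_threshold)
        return Attractor("limit_cycle", rep, period, 1, sig)
    drift = float(np.linalg.norm(orbit[-1] - orbit[-2]))
    return Attractor(
        "unresolved",
        orbit[-1],
        None,
        1,
        (),
        diagnostics=f"no convergence or consistent recurrence; last frame step {drift:.2e}",
    )


def _visit_signature(orbit, params, targets, sim_threshold):
    """Sorted tuple of target indices the orbit output approaches."""
    if not targets:
        return ()
    out = orbit[:, params.N_hid :]
    norms = np.linalg.norm(out, axis=1)
    norms[norms == 0] = 1.0
    sig = []
    for k, tgt in enumerate(targets):
        tgt = np.asarray(tgt, dtype=float)
        ov = out @ tgt / (norms * np.linalg.norm(tgt))
        if (ov > sim_threshold).any():
            sig.append(k)
    return tuple(sig)


def attractor_census(
    w: SynapticWeights,
    input: np.ndarray | None,
    gamma: float,
    params: NetworkParams,
    M: int = 50,
    seed: int | np.random.Generator = 0,
    transient: float = 200.0,
    horizon: float = 2000.0,
    tol_fp: float = 1e-6,
    tol_cycle: float = 1e-3,
    merge_tol: float = 0.05,
    targets: list[np.ndarray] | None = None,
    sim_threshold: float = 0.9,
) -> list[Attractor]:
    """Census of distinct attractors from ``M`` random initial states.

    All trajectories run the transient as one batch; trajectories whose
    drift has converged are classified as fixed points directly, the
    rest are resolved individually.  Fixed points merge when their
    states are within ``merge_tol``; limit cycles merge on equal
    visited-target signature and period within 10%.  Basin counts sum
    to the number of resolved trials.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w.check_shapes(params)
    lo, hi = 1e-6, 1 - 1e-6
    Xh = np.ascontiguousarray(rng.uniform(lo, hi, (params.N_hid, M)))
    Xo = np.ascontiguousarray(rng.uniform(lo, hi, (params.N_out, M)))
    I_ext = _external_drive(w, input, gamma, params, M)
    _relax_batch(Xh, Xo, w, I_ext, params, transient)
    # chunked relaxation with convergence drop-out
    remaining = np.arange(M)
    found: list[Attractor] = []
    chunk = 100.0
    done = 0.0
    budget = horizon - transient
    while done < budget and remaining.size:
        T = min(chunk, budget - done)
        _relax_batch(Xh, Xo, w, I_ext, params, T)
        done += T
        drift = _batch_drift(Xh, Xo, w, I_ext, params)
        conv = drift < tol_fp
        for idx in np.where(conv)[0]:
            rep = np.concatenate([Xh[:, idx], Xo[:, idx]])
            sig = _visit_signature(rep[None, :], params, targets, sim_threshold)
            found.append(Attractor("fixed_point", rep, None, 1, sig))
        keep = ~conv
        if conv.any():
            Xh = np.ascontiguousarray(Xh[:, keep])
            Xo = np.ascontiguousarray(Xo[:, keep])
            I_ext = np.ascontiguousarray(I_ext[:, keep])
            remaining = remaining[keep]
    # unconverged trajectories: look for cycles, one by one
    for b in range(remaining.size):
        xh = np.ascontiguousarray(Xh[:, b : b + 1].copy())
        xo = np.ascontiguousarray(Xo[:, b : b + 1].copy())
        ie = np.ascontiguousarray(I_ext[:, b : b + 1])
        times, states = _record_window(xh, xo, w, ie, params, 600.0, 25)
        hit = _classify_cycle(times, states[:, :, 0], tol_cycle)
        if hit is not None:
            period, i0, i1 = hit
            rep = states[i0:i1, :, 0]
            sig = _visit_signature(rep, params, targets, sim_threshold)
            found.append(Attractor("limit_cycle", rep, period, 1, sig))
        else:
            found.append(
                Attractor("unresolved", states[-1, :, 0], None, 1, (),
                          diagnostics="no convergence within horizon")
            )
    return _merge_attractors(found, merge_tol)


def _batch_drift(Xh, Xo, w, I_ext, params):
    I_h = I_ext + w.J_oh @ Xo + params.c_inh * (Xh.sum(axis=0) - Xh)
    I_o = w.J_ho @ Xh + params.c_inh * (Xo.sum(axis=0) - Xo)
    with np.errstate(over="ignore"):
        f = lambda u: 1.0 / (1.0 + np.exp(-params.beta * (u - params.theta)))
        return np.maximum(
            np.abs(-Xh + f(I_h)).max(axis=0), np.abs(-Xo + f(I_o)).max(axis=0)
        )


def _merge_attractors(found: list[Attractor], merge_tol: float) -> list[Attractor]:
    merged: list[Attractor] = []
    for a in found:
        hit = None
        for m in merged:
            if m.kind != a.kind:
                continue
            if a.kind == "fixed_point":
                if np.linalg.norm(a.representative - m.representative) / np.sqrt(
                    a.representative.size
                ) < merge_tol:
                    hit = m
                    break
            elif a.kind == "limit_cycle":
                if (
                    a.signature == m.signature
                    and m.period is not None
                    and a.period is not None
                    and abs(a.period - m.period) <= 0.1 * max(a.period, m.period)
                ):
                    hit = m
                    break
            else:  # unresolved merge on proximity, keeps census finite
                if np.linalg.norm(a.representative - m.representative) / np.sqrt(
                    a.representative.size
                ) < merge_tol:
                    hit = m
                    break
        if hit is None:
            merged.append(a)
        else:
            hit.basin_count += a.basin_count
    return merged


def itinerancy_sequence(
    trajectory: Trajectory,
    targets: list[np.ndarray],
    sim_threshold: float = 0.9,
) -> ItinerarySequence:
    """Maximal intervals during which the output tracks some target.

    At each recorded time the output's normalized overlap with every
    target is computed; a visit is a maximal run of samples with some
    overlap above ``sim_threshold``.  If several targets exceed it
    simultaneously the largest overlap wins (ties: lowest index).
    """
    if not targets:
        raise ValueError("need at least one learned target")
    out = trajectory.output
    times = trajectory.times
    norms = np.linalg.norm(out, axis=1)
    norms[norms == 0] = 1.0
    T = np.stack([np.asarray(t, dtype=float) for t in targets], axis=1)
    ovl = (out @ T) / (norms[:, None] * np.linalg.norm(T, axis=0)[None, :])
    best = np.argmax(ovl, axis=1)
    best_val = ovl[np.arange(len(out)), best]
    active = best_val > sim_threshold
    visits: list[ItineraryVisit] = []
    cur_id, t_in = None, 0.0
    for i in range(len(times)):
        tid = int(best[i]) if active[i] else None
        if tid != cur_id:
            if cur_id is not None:
                visits.append(ItineraryVisit(cur_id, t_in, float(times[i])))
            cur_id = tid
            t_in = float(times[i])
    if cur_id is not None:
        visits.append(ItineraryVisit(cur_id, t_in, float(times[-1])))
    return ItinerarySequence(visits)


def evoked_reference_states(
    w: SynapticWeights,
    mappings: list[IOMapping],
    params: NetworkParams,
    seed: int | np.random.Generator = 0,
    T_max: float = 300.0,
    tol_fp: float = 1e-7,
) -> tuple[np.ndarray, list[int]]:
    """Converged evoked state per mapping (hidden+output concatenated).

    Each mapping's input is clamped at ``gamma_learn`` and one random
    initial state is relaxed to convergence.  Returns the reference
    array (n_mappings, N_hid+N_out) and the list of mapping indices
    that failed to converge (their rows are the final states reached).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    refs = np.empty((len(mappings), params.N_hid + params.N_out))
    unresolved = []
    for k, mp in enumerate(mappings):
        st = random_state(params, rng)
        Xh = np.ascontiguousarray(st.x_hidden[:, None])
        Xo = np.ascontiguousarray(st.x_output[:, None])
        I_ext = _external_drive(w, mp.input, params.gamma_learn, params, 1)
        steps = _relax_batch(Xh, Xo, w, I_ext, params, T_max, conv_tol=tol_fp)
        if steps >= int(round(T_max / params.dt)):
            unresolved.append(k)
        refs[k] = np.concatenate([Xh[:, 0], Xo[:, 0]])
    return refs, unresolved


def min_distance_profile(
    w: SynapticWeights,
    mappings: list[IOMapping],
    params: NetworkParams,
    n_init: int = 1000,
    seed: int | np.random.Generator = 0,
    horizon: float = 500.0,
    ref_seed: int | None = None,
    refs: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Per-target D_min of spontaneous orbits, averaged over initials.

    For each mapping, the reference is its converged evoked state
    (hidden and output layers), computed from ``w`` — or supplied
    explicitly via ``refs`` (rows per mapping), e.g. references from
    the fully trained network when profiling an earlier learning stage.
    ``n_init`` random initial states are relaxed with no input for
    ``horizon``, tracking for each the minimum over time of
    ``|x - X_ref| / |X_ref|``; the average over initial states is
    returned per target, along with indices of mappings whose evoked
    simulation did not converge.
    """
    if not mappings:
        raise ValueError("need at least one learned target")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if refs is not None:
        refs = np.asarray(refs, dtype=float)
        if refs.shape != (len(mappings), params.N_hid + params.N_out):
            raise ValueError("refs shape must be (n_mappings, N_hid+N_out)")
        unresolved: list[int] = []
    else:
        ref_rng = np.random.default_rng(ref_seed) if ref_seed is not None else rng
        refs, unresolved = evoked_reference_states(w, mappings, params, seed=ref_rng)
    K = len(mappings)
    lo, hi = 1e-6, 1 - 1e-6
    Xh = np.ascontiguousarray(rng.uniform(lo, hi, (params.N_hid, n_init)))
    Xo = np.ascontiguousarray(rng.uniform(lo, hi, (params.N_out, n_init)))
    I_ext = np.zeros((params.N_hid, n_init))
    refs_h = np.ascontiguousarray(refs[:, : params.N_hid].T)
    refs_o = np.ascontiguousarray(refs[:, params.N_hid :].T)
    ref_norms = np.linalg.norm(refs, axis=1)
    Dmin = np.full((K, n_init), np.inf)
    _kernels.relax_track_min(
        Xh, Xo, w.J_ho, w.J_oh, I_ext, refs_h, refs_o, ref_norms,
        params.c_inh, params.beta, params.theta, params.tau, params.dt,
        int(round(horizon / params.dt)), Dmin,
    )
    return Dmin.mean(axis=1), unresolved


def jacobian_eigenvalues(
    state_vec: np.ndarray,
    w: SynapticWeights,
    input: np.ndarray | None,
    gamma: float,
    params: NetworkParams,
) -> np.ndarray:
    """Eigenvalues of the linearized relaxation at a candidate fixed point.

    The Jacobian of ``dx/dt = (-x + f(I(x))) / tau`` for the coupled
    hidden+output system; all real parts negative certifies linear
    stability.
    """
    Nh, No = params.N_hid, params.N_out
    xh, xo = state_vec[:Nh], state_vec[Nh:]
    I_h = w.J_oh @ xo + params.c_inh * (xh.sum() - xh)
    if input is not None:
        I_h = I_h + gamma * (w.J_ih @ np.asarray(input, dtype=float))
    I_o = w.J_ho @ xh + params.c_inh * (xo.sum() - xo)
    f = lambda u: 1.0 / (1.0 + np.exp(-params.beta * (u - params.theta)))
    fp_h = params.beta * f(I_h) * (1 - f(I_h))
    fp_o = params.beta * f(I_o) * (1 - f(I_o))
    C_hh = params.c_inh * (np.ones((Nh, Nh)) - np.eye(Nh))
    C_oo = params.c_inh * (np.ones((No, No)) - np.eye(No))
    J = np.zeros((Nh + No, Nh + No))
    J[:Nh, :Nh] = fp_h[:, None] * C_hh
    J[:Nh, Nh:] = fp_h[:, None] * w.J_oh
    J[Nh:, :Nh] = fp_o[:, None] * w.J_ho
    J[Nh:, Nh:] = fp_o[:, None] * C_oo
    J -= np.eye(Nh + No)
    J /= params.tau
    return np.linalg.eigvals(J)
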