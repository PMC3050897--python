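"""Sequential curriculum learning and memory-capacity measurement.

Each learning step presents one input->target mapping with the input
clamped at strength ``gamma_learn``.  While the output is far from the
target (``d >= eps_d``) the anti-Hebbian rule destabilizes the ongoing
activity and the network itinerates — the *search phase*; once the
output falls within ``eps_d`` of the target the Hebbian rule locks it
in — the *stabilization phase*.  A step succeeds when the error has
stayed below ``eps_d`` for a contiguous ``T_stab``, and times out at
``T_max``.

A mapping counts as *memorized* when, with frozen weights, its input
drives the output to within ``eps_d`` of its target from more than half
of random initial states.  Capacity is the maximum over learning steps
of the number of memorized mappings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dynamics import NetworkState, SynapticWeights, random_state
from .params import NetworkParams
from .patterns import IOMapping

__all__ = [
    "LearningTrace",
    "CapacityCurve",
    "CurriculumResult",
    "ResidenceStats",
    "run_learning_step",
    "recall_fractions",
    "is_memorized",
    "run_curriculum",
    "residence_time",
]


@dataclass
class LearningTrace:
    """Decimated record of one learning step.

    ``phase_series`` holds 1 during stabilization (``d < eps_d``) and 0
    during search; ``output`` the output-layer rates at the recorded
    times.
    """

    times: np.ndarray
    d_series: np.ndarray
    phase_series: np.ndarray
    output: np.ndarray
    mapping_id: int
    success: bool
    duration: float

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.d_series) == len(self.phase_series) == len(self.output) == n):
            raise ValueError("trace series lengths disagree")


@dataclass
class CapacityCurve:
    """Number of memorized mappings after each learning step."""

    counts: list[int]

    def __post_init__(self) -> None:
        for k, c in enumerate(self.counts):
            if not 0 <= c <= k + 1:
                raise ValueError(f"count {c} after step {k + 1} is impossible")

    @property
    def capacity(self) -> int:
        return max(self.counts) if self.counts else 0


@dataclass
class CurriculumResult:
    """Everything produced by one sequential learning run."""

    capacity_curve: CapacityCurve
    weight_history: list[SynapticWeights]
    traces: list[LearningTrace]
    statuses: list[str]  # "success" or "timeout" per step
    fractions: list[np.ndarray]  # per step: recall fraction of each mapping so far
    params: NetworkParams
    seed: int

    @property
    def capacity(self) -> int:
        return self.capacity_curve.capacity


@dataclass
class ResidenceStats:
    """Mean contiguous time per visit near previously learned targets."""

    mean_time: float
    n_visits: int
    visited: bool


def run_learning_step(
    w: SynapticWeights,
    state: NetworkState,
    mapping: IOMapping,
    params: NetworkParams,
    T_stab: float = 600.0,
    T_max: float = 40000.0,
    record_every: int = 10,
    bs_stab_scale: float = 0.02,
) -> tuple[SynapticWeights, NetworkState, LearningTrace]:
    """One coupled dynamics+plasticity step on a single mapping.

    Runs until the error has stayed below ``eps_d`` for a contiguous
    ``T_stab`` (success) or until ``T_max`` (timeout — reported in the
    trace, not raised).  ``bs_stab_scale`` scales backward-synapse
    plasticity during the stabilization phase: 0 freezes the backward
    synapses while the pattern consolidates (only forward synapses
    vary), 1 leaves them fully plastic.  Weights and state are not
    modified in place; new objects are returned.
    """
    if not T_max > T_stab > 0:
        raise ValueError("need T_max > T_stab > 0")
    w.check_shapes(params)
    w = w.copy()
    xh = state.x_hidden.copy()
    xo = state.x_output.copy()
    n_stab = int(round(T_stab / params.dt))
    n_max = int(round(T_max / params.dt))
    n_frames = n_max // record_every + 2
    d_rec = np.empty(n_frames)
    phase_rec = np.empty(n_frames, dtype=np.int64)
    out_rec = np.empty((n_frames, params.N_out))
    success, steps, n_rec = _kernels.learn_step(
        xh,
        xo,
        w.J_ih,
        w.J_ho,
        w.J_oh,
        mapping.input,
        mapping.target,
        params.gamma_learn,
        params.c_inh,
        params.beta,
        params.theta,
        params.tau,
        params.dt,
        params.r0,
        params.eps_d,
        params.lambda_penalty,
        params.tau_f,
        params.tau_b,
        params.w_max,
        n_stab,
        n_max,
        bs_stab_scale,
        record_every,
        d_rec,
        phase_rec,
        out_rec,
    )
    trace = LearningTrace(
        times=state.t + params.dt * record_every * np.arange(n_rec),
        d_series=d_rec[:n_rec].copy(),
        phase_series=phase_rec[:n_rec].copy(),
        output=out_rec[:n_rec].copy(),
        mapping_id=mapping.id,
        success=bool(success),
        duration=params.dt * steps,
    )
    new_state = NetworkState(xh, xo, state.t + params.dt * steps)
    return w, new_state, trace


def recall_fractions(
    w: SynapticWeights,
    mappings: list[IOMapping],
    params: NetworkParams,
    K: int = 20,
    seed: int | np.random.Generator = 0,
    T_recall: float = 100.0,
    conv_tol: float = 1e-7,
    chunk: float = 10.0,
) -> np.ndarray:
    """Fraction of random initial states recalling each mapping.

    For every mapping, ``K`` random initial states are relaxed with the
    input clamped at ``gamma_learn`` and frozen weights, until the
    drift per ``tau`` of every trajectory falls below ``conv_tol`` or
    the horizon ``T_recall`` is reached; a trial recalls when its final
    output lies within ``eps_d`` of the target.  All mappings and
    trials run as one batch; converged trajectories drop out between
    chunks of duration ``chunk``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not mappings:
        return np.zeros(0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = len(mappings)
    B = M * K
    Nh, No = params.N_hid, params.N_out
    lo, hi = 1e-6, 1 - 1e-6
    Xh = np.ascontiguousarray(rng.uniform(lo, hi, (Nh, B)))
    Xo = np.ascontiguousarray(rng.uniform(lo, hi, (No, B)))
    I_ext = np.empty((Nh, B))
    for m, mp in enumerate(mappings):
        drive = params.gamma_learn * (w.J_ih @ mp.input)
        I_ext[:, m * K : (m + 1) * K] = drive[:, None]
    I_ext = np.ascontiguousarray(I_ext)
    n_total = int(round(T_recall / params.dt))
    n_chunk = max(1, int(round(chunk / params.dt)))
    dummy = np.empty((0, 1, 1))
    active = np.arange(B)
    final_Xo = np.empty((No, B))
    done = 0
    while done < n_total and active.size:
        n_run = min(n_chunk, n_total - done)
        _kernels.relax(
            Xh,
            Xo,
            w.J_ho,
            w.J_oh,
            I_ext,
            params.c_inh,
            params.beta,
            params.theta,
            params.tau,
            params.dt,
            n_run,
            0.0,
            0,
            dummy,
            dummy,
        )
        done += n_run
        # drift per tau of each remaining trajectory (one explicit evaluation)
        I_h = I_ext + w.J_oh @ Xo + params.c_inh * (Xh.sum(axis=0) - Xh)
        I_o = w.J_ho @ Xh + params.c_inh * (Xo.sum(axis=0) - Xo)
        with np.errstate(over="ignore"):
            f = lambda u: 1.0 / (1.0 + np.exp(-params.beta * (u - params.theta)))
            drift = np.maximum(
                np.abs(-Xh + f(I_h)).max(axis=0), np.abs(-Xo + f(I_o)).max(axis=0)
            )
        conv = drift < conv_tol
        if conv.any():
            final_Xo[:, active[conv]] = Xo[:, conv]
            keep = ~conv
            Xh = np.ascontiguousarray(Xh[:, keep])
            Xo = np.ascontiguousarray(Xo[:, keep])
            I_ext = np.ascontiguousarray(I_ext[:, keep])
            active = active[keep]
    if active.size:
        final_Xo[:, active] = Xo
    fractions = np.empty(M)
    for m, mp in enumerate(mappings):
        outs = final_Xo[:, m * K : (m + 1) * K]
        d = np.linalg.norm(outs - mp.target[:, None], axis=0) / np.linalg.norm(
            mp.target
        )
        fractions[m] = np.mean(d < params.eps_d)
    return fractions


def is_memorized(
    w: SynapticWeights,
    mapping: IOMapping,
    params: NetworkParams,
    K: int = 20,
    threshold_frac: float = 0.5,
    seed: int | np.random.Generator = 0,
    T_recall: float = 100.0,
) -> tuple[bool, float]:
    """Whether the mapping's input evokes its target from most states.

    Returns ``(memorized, fraction)`` where ``memorized`` requires the
    recall fraction to exceed ``threshold_frac`` strictly.
    """
    frac = float(
        recall_fractions(w, [mapping], params, K=K, seed=seed, T_recall=T_recall)[0]
    )
    return frac > threshold_frac, frac


def run_curriculum(
    params: NetworkParams,
    curriculum: list[IOMapping],
    seed: int = 0,
    init_weights: str = "zero",
    T_stab: float = 600.0,
    T_max: float = 40000.0,
    K: int = 20,
    T_recall: float = 100.0,
    record_every: int = 10,
    keep_traces: bool = True,
    bs_stab_scale: float = 0.02,
) -> CurriculumResult:
    """Learn an ordered curriculum one mapping at a time.

    After every learning step each mapping learned so far is tested for
    memorization; the capacity curve collects the counts.  Initial
    weights are ``"zero"`` or ``"uniform01"``; the initial state and
    all recall-test states derive from ``seed``.
    """
    if not curriculum:
        raise ValueError("curriculum must be nonempty")
    if len({m.id for m in curriculum}) != len(curriculum):
        raise ValueError("mapping ids must be distinct")
    rng = np.random.default_rng(seed)
    if init_weights == "zero":
        w = SynapticWeights.zeros(params)
    elif init_weights == "uniform01":
        w = SynapticWeights.uniform(params, rng)
    else:
        raise ValueError(f"unknown init_weights {init_weights!r}")
    state = random_state(params, rng)
    counts: list[int] = []
    weight_history: list[SynapticWeights] = []
    traces: list[LearningTrace] = []
    statuses: list[str] = []
    fractions: list[np.ndarray] = []
    for k, mapping in enumerate(curriculum):
        w, state, trace = run_learning_step(
            w, state, mapping, params, T_stab=T_stab, T_max=T_max,
            record_every=record_every, bs_stab_scale=bs_stab_scale,
        )
        statuses.append("success" if trace.success else "timeout")
        weight_history.append(w.copy())
        if keep_traces:
            traces.append(trace)
        frac = recall_fractions(
            w, curriculum[: k + 1], params, K=K, seed=rng, T_recall=T_recall
        )
        fractions.append(frac)
        counts.append(int(np.sum(frac > 0.5)))
    return CurriculumResult(
        CapacityCurve(counts), weight_history, traces, statuses, fractions,
        params, seed,
    )


def residence_time(
    trace,
    targets: list[np.ndarray],
    sim_threshold: float = 0.9,
    search_only: bool = True,
    tau_b: float | None = None,
) -> ResidenceStats:
    """Mean contiguous time per visit near previously learned targets.

    A visit is a maximal interval during which the output's normalized
    overlap with *some* target exceeds ``sim_threshold``.  For a
    ``LearningTrace`` only search-phase samples count by default (the
    itinerant regime); a ``Trajectory`` is used in full.  If ``tau_b``
    is given, the mean is divided by it for cross-timescale comparison.
    """
    if not targets:
        raise ValueError("need at least one learned target")
    times = np.asarray(trace.times, dtype=float)
    output = np.asarray(trace.output, dtype=float)
    if len(times) == 0:
        return ResidenceStats(0.0, 0, False)
    norms = np.linalg.norm(output, axis=1)
    norms[norms == 0] = 1.0
    near = np.zeros(len(times), dtype=bool)
    for tgt in targets:
        tgt = np.asarray(tgt, dtype=float)
        ov = (output @ tgt) / (norms * np.linalg.norm(tgt))
        near |= ov > sim_threshold
    if search_only and hasattr(trace, "phase_series"):
        near &= np.asarray(trace.phase_series) == 0
    # contiguous visits on the sampled grid
    step = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    total = 0.0
    n_visits = 0
    in_visit = False
    for flag in near:
        if flag:
            total += step
            if not in_visit:
                n_visits += 1
                in_visit = True
        else:
            in_visit = False
    if n_visits == 0:
        return ResidenceStats(0.0, 0, False)
    mean = total / n_visits
    if tau_b is not None:
        mean /= tau_b
    return ResidenceStats(mean, n_visits, True)
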