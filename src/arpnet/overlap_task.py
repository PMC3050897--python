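"""The overlapping-input extension task (2 inputs -> 3 outputs).

The standard task uses disjoint one-hot inputs.  Here the three input
patterns (1,0), (0,1) and (1,1) over two input neurons overlap — the
third contains both others — and map to one-hot targets (1,0,0),
(0,1,0), (0,0,1) over three output neurons.  Because a synapse serving
input 1 alone also conducts when (1,1) is applied, the task is only
solvable when synaptic strengths saturate at a finite upper bound
``w_max``: the bound forces the hidden code for (1,1) onto a unit that
needs *both* inputs to win the competition.  The curriculum is
presented repeatedly (bounded weights make repetition safe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SynapticWeights, random_state
from .params import NetworkParams
from .patterns import IOMapping, generate_overlap_task
from .protocol import recall_fractions, run_learning_step

__all__ = ["OverlapTaskResult", "overlap_params", "run_overlap_task"]


def overlap_params(
    n_hidden: int = 6,
    w_max: float = 1.0,
    **overrides,
) -> NetworkParams:
    """Parameters for the bounded-weight overlapping-input network.

    Two input neurons, ``n_hidden`` hidden neurons and three output
    neurons; every plastic weight is clipped to ``[0, w_max]``.
    """
    defaults = dict(
        N=3,
        n_input=2,
        n_hidden=n_hidden,
        n_output=3,
        w_max=w_max,
    )
    defaults.update(overrides)
    return NetworkParams(**defaults)


@dataclass
class OverlapTaskResult:
    params: NetworkParams
    curriculum: list[IOMapping]
    statuses: list[str]
    recall: np.ndarray  # final recall fraction per mapping
    weights: SynapticWeights
    seed: int
    n_steps: int = 0

    @property
    def all_recalled(self) -> bool:
        return bool(np.all(self.recall > 0.5))

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "n_steps": self.n_steps,
            "statuses": self.statuses,
            "recall_fractions": [float(x) for x in self.recall],
            "all_recalled": self.all_recalled,
            "w_max": self.params.w_max,
            "n_hidden": self.params.N_hid,
        }


def run_overlap_task(
    seed: int = 0,
    max_steps: int = 200,
    params: NetworkParams | None = None,
    T_stab_consolidate: float = 300.0,
    T_max_consolidate: float = 8000.0,
    T_stab_graft: float = 10.0,
    T_burst: float = 300.0,
    K: int = 40,
    bs_stab_scale: float = 0.02,
) -> OverlapTaskResult:
    """Learn the three overlapping mappings with bounded weights.

    The two disjoint mappings are first consolidated with long
    stabilization phases.  The overlapping mapping (1,1) -> (0,0,1) is
    then grafted in short bursts with a brief stabilization: its shared
    forward weights must end up *between* half of and the full strength
    of the consolidated codes (above the bound's midpoint, below the
    bound), a band that long Hebbian phases overshoot.  After every
    presentation all three mappings are recall-tested (``K`` random
    initial states each); rehearsal returns to any mapping the graft
    has broken, and learning stops the moment all three are recalled
    simultaneously, or after ``max_steps`` presentations.
    """
    if params is None:
        params = overlap_params()
    if not np.isfinite(params.w_max):
        raise ValueError("the overlapping-input task requires finite w_max")
    curriculum = generate_overlap_task()
    rng = np.random.default_rng(seed)
    w = SynapticWeights.zeros(params)
    state = random_state(params, rng)
    statuses: list[str] = []
    recall = np.zeros(len(curriculum))
    n_steps = 0
    consolidated = [False, False]
    while n_steps < max_steps:
        recall = recall_fractions(w, curriculum, params, K=K, seed=rng)
        if np.all(recall > 0.5):
            break
        if recall[0] <= 0.5 or recall[1] <= 0.5:
            # (re-)consolidate the first broken disjoint mapping
            k = 0 if recall[0] <= 0.5 else 1
            w, state, trace = run_learning_step(
                w, state, curriculum[k], params,
                T_stab=T_stab_consolidate, T_max=T_max_consolidate,
                bs_stab_scale=bs_stab_scale,
            )
            consolidated[k] = trace.success
        else:
            # disjoint codes in place: graft the overlapping mapping
            w, state, trace = run_learning_step(
                w, state, curriculum[2], params,
                T_stab=T_stab_graft, T_max=T_burst,
                bs_stab_scale=bs_stab_scale,
            )
        statuses.append("success" if trace.success else "timeout")
        n_steps += 1
    else:
        recall = recall_fractions(w, curriculum, params, K=K, seed=rng)
    return OverlapTaskResult(params, curriculum, statuses, recall, w, seed, n_steps)
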