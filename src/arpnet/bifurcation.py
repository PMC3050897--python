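"""Attractor changes under varying input strength.

Recall in this model is a bifurcation: as the strength ``gamma`` of a
clamped input grows, the spontaneous attractor loses stability and a
fixed point whose output matches the learned target appears (by a
saddle-node bifurcation in the simplest case).  Because attractors
coexist over intervals of ``gamma``, up- and down-continued sweeps can
disagree — hysteresis.  With two learned inputs applied together the
reached attractor is classified into phases (fixed point matching A or
B, their coexistence, limit cycles approaching A, B or neither).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attractors import Attractor, attractor_census, find_attractor, overlap
from .dynamics import NetworkState, SynapticWeights, random_state
from .params import NetworkParams
from .patterns import IOMapping

__all__ = [
    "BifurcationBranch",
    "sweep_input_strength",
    "two_input_phase_diagram",
    "PHASE_LABELS",
]

PHASE_LABELS = ("FA", "FB", "FA_plus_FB", "LA", "LB", "LN", "spontaneous", "other")


@dataclass
class BifurcationBranch:
    """Result of one input-strength sweep against one probed target.

    Per grid point: the kinds of the reached attractors, the best
    overlap of a reached attractor's output with the target, and
    whether a target-matching fixed point was reached.  ``gamma_star``
    is the smallest grid strength at which it was (None if never).
    """

    gamma_grid: np.ndarray
    kinds: list[tuple[str, ...]]
    target_overlap: np.ndarray
    matched: np.ndarray
    mode: str
    gamma_star: float | None

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma_grid, dtype=float)
        if len(g) > 1 and not np.all(np.diff(g) > 0):
            raise ValueError("gamma grid must be strictly increasing")


def _matches_target(att: Attractor, target: np.ndarray, params: NetworkParams) -> bool:
    """Fixed point whose output lies within eps_d of the target."""
    if att.kind != "fixed_point":
        return False
    out = att.output_part(params)
    d = np.linalg.norm(out - target) / np.linalg.norm(target)
    return bool(d < params.eps_d)


def sweep_input_strength(
    w: SynapticWeights,
    input: np.ndarray,
    target: np.ndarray,
    params: NetworkParams,
    gamma_grid: np.ndarray | None = None,
    mode: str = "independent",
    n_init: int = 10,
    seed: int | np.random.Generator = 0,
    transient: float = 200.0,
    horizon: float = 1200.0,
) -> BifurcationBranch:
    """Sweep the clamped-input strength and record reached attractors.

    ``independent`` mode draws ``n_init`` fresh random initial states
    at every grid point (superposed-starts bifurcation diagram);
    ``continued_up`` / ``continued_down`` carry the final state from
    one grid point to the next (hysteresis probe), traversing the grid
    in ascending / descending order.
    """
    if gamma_grid is None:
        gamma_grid = np.linspace(0.0, 2.0 * params.gamma_learn, 50)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if mode not in ("independent", "continued_up", "continued_down"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = np.asarray(target, dtype=float)
    kinds: list[tuple[str, ...]] = [()] * len(gamma_grid)
    best_ov = np.zeros(len(gamma_grid))
    matched = np.zeros(len(gamma_grid), dtype=bool)

    if mode == "independent":
        for i, g in enumerate(gamma_grid):
            atts = attractor_census(
                w, input, g, params, M=n_init, seed=rng,
                transient=transient, horizon=horizon,
            )
            kinds[i] = tuple(a.kind for a in atts)
            ovs = []
            for a in atts:
                out = a.output_part(params)
                out2 = out if out.ndim == 2 else out[None, :]
                ovs.append(max(overlap(o, target) for o in out2))
                if _matches_target(a, target, params):
                    matched[i] = True
            best_ov[i] = max(ovs) if ovs else 0.0
    else:
        order = range(len(gamma_grid))
        if mode == "continued_down":
            order = range(len(gamma_grid) - 1, -1, -1)
        state = random_state(params, rng)
        for i in order:
            att = find_attractor(
                w, input, float(gamma_grid[i]), state, params,
                transient=transient, horizon=horizon,
            )
            kinds[i] = (att.kind,)
            rep = att.representative
            last = rep if rep.ndim == 1 else rep[-1]
            out = last[params.N_hid :]
            outs = rep[:, params.N_hid :] if rep.ndim == 2 else out[None, :]
            best_ov[i] = max(overlap(o, target) for o in outs)
            matched[i] = _matches_target(att, target, params)
            # seed the next grid point with the state just reached
            state = NetworkState(
                np.clip(last[: params.N_hid], 1e-9, 1 - 1e-9),
                np.clip(last[params.N_hid :], 1e-9, 1 - 1e-9),
            )
    gamma_star = None
    hits = np.where(matched)[0]
    if hits.size:
        gamma_star = float(gamma_grid[hits[0]])
    return BifurcationBranch(gamma_grid, kinds, best_ov, matched, mode, gamma_star)


def two_input_phase_diagram(
    w: SynapticWeights,
    mapping_a: IOMapping,
    mapping_b: IOMapping,
    params: NetworkParams,
    gammaA_grid: np.ndarray,
    gammaB_grid: np.ndarray,
    n_init: int = 10,
    seed: int | np.random.Generator = 0,
    sim_threshold: float = 0.9,
    transient: float = 200.0,
    horizon: float = 1200.0,
) -> np.ndarray:
    """Phase labels on a (gammaA, gammaB) grid of summed clamped inputs.

    At each cell a census from ``n_init`` random states runs with input
    ``gammaA * xiA + gammaB * xiB`` clamped.  Labels: ``FA``/``FB`` if
    the only attractors are fixed points matching A (resp. B);
    ``FA_plus_FB`` if both matching fixed points coexist; ``LA``/``LB``
    if a limit cycle approaches A (resp. B) above ``sim_threshold``;
    ``LN`` for a limit cycle approaching neither; ``spontaneous`` at
    the origin; ``other`` otherwise (including unresolved cells).

    Returns an object array of shape (len(gammaA_grid), len(gammaB_grid)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gammaA_grid = np.asarray(gammaA_grid, dtype=float)
    gammaB_grid = np.asarray(gammaB_grid, dtype=float)
    xiA, xiB = mapping_a.input, mapping_b.input
    tA, tB = mapping_a.target, mapping_b.target
    labels = np.empty((len(gammaA_grid), len(gammaB_grid)), dtype=object)
    for i, ga in enumerate(gammaA_grid):
        for j, gb in enumerate(gammaB_grid):
            if ga == 0.0 and gb == 0.0:
                labels[i, j] = "spontaneous"
                continue
            combo = ga * xiA + gb * xiB
            atts = attractor_census(
                w, combo, 1.0, params, M=n_init, seed=rng,
                transient=transient, horizon=horizon,
                targets=[tA, tB], sim_threshold=sim_threshold,
            )
            labels[i, j] = _phase_label(atts, tA, tB, params)
    return labels


def _phase_label(atts: list[Attractor], tA, tB, params) -> str:
    has_fa = any(_matches_target(a, tA, params) for a in atts)
    has_fb = any(_matches_target(a, tB, params) for a in atts)
    cycles = [a for a in atts if a.kind == "limit_cycle"]
    others = [
        a
        for a in atts
        if a.kind == "unresolved"
        or (
            a.kind == "fixed_point"
            and not _matches_target(a, tA, params)
            and not _matches_target(a, tB, params)
        )
    ]
    if has_fa and has_fb:
        return "FA_plus_FB"
    if has_fa and not cycles and not others:
        return "FA"
    if has_fb and not cycles and not others:
        return "FB"
    if cycles:
        visits_a = any(0 in c.signature for c in cycles)
        visits_b = any(1 in c.signature for c in cycles)
        if visits_a and not visits_b:
            return "LA"
        if visits_b and not visits_a:
            return "LB"
        if not visits_a and not visits_b:
            return "LN"
    return "other"
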