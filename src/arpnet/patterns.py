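"""Binary input/target patterns and curriculum generation.

A pattern is a binary (0/1) vector with at least one active unit.  The
standard learning task uses sparse one-hot patterns: a single active
neuron codes each input and each target.  The overlapping-input
extension task uses two input neurons and three output neurons, with
the third input ``(1, 1)`` overlapping the first two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "as_pattern",
    "IOMapping",
    "generate_onehot_curriculum",
    "generate_overlap_task",
]


def as_pattern(bits, n: int | None = None) -> np.ndarray:
    """Validate and return a binary pattern as a float array.

    Raises ``ValueError`` if any element is outside {0, 1}, if the
    pattern is all-zero, or if ``n`` is given and the length differs.
    """
    arr = np.asarray(bits, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"pattern must be 1-D, got shape {arr.shape}")
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError("pattern elements must be 0 or 1")
    if not arr.any():
        raise ValueError("pattern must have at least one active unit")
    if n is not None and arr.size != n:
        raise ValueError(f"pattern length {arr.size} != expected {n}")
    return arr


@dataclass(frozen=True)
class IOMapping:
    """One input->target association of the curriculum."""

    input: np.ndarray
    target: np.ndarray
    id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "input", as_pattern(self.input))
        object.__setattr__(self, "target", as_pattern(self.target))


def generate_onehot_curriculum(
    N: int, m: int, seed: int, rng: np.random.Generator | None = None
) -> list[IOMapping]:
    """Draw ``m`` mappings with distinct one-hot inputs and targets.

    The input->target pairing is a seeded random bijection between
    ``m`` distinct input neurons and ``m`` distinct target neurons.

    Raises ``ValueError`` when ``m > N`` (one-hot coding admits at most
    ``N`` distinct patterns per layer).
    """
    if not 1 <= m <= N:
        raise ValueError(
            f"m={m} mappings cannot use distinct one-hot patterns of size N={N}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    in_units = rng.permutation(N)[:m]
    out_units = rng.permutation(N)[:m]
    curriculum = []
    for k in range(m):
        inp = np.zeros(N)
        tgt = np.zeros(N)
        inp[in_units[k]] = 1.0
        tgt[out_units[k]] = 1.0
        curriculum.append(IOMapping(inp, tgt, id=k))
    return curriculum


def generate_overlap_task() -> list[IOMapping]:
    """The three-mapping overlapping-input task.

    Inputs ``(1,0)``, ``(0,1)`` and ``(1,1)`` over two input neurons map
    to one-hot targets ``(1,0,0)``, ``(0,1,0)`` and ``(0,0,1)`` over
    three output neurons.  The third input overlaps both of the others,
    so the task is solvable only with a finite upper bound on the
    synaptic strength.
    """
    return [
        IOMapping(np.array([1.0, 0.0]), np.array([1.0, 0.0, 0.0]), id=0),
        IOMapping(np.array([0.0, 1.0]), np.array([0.0, 1.0, 0.0]), id=1),
        IOMapping(np.array([1.0, 1.0]), np.array([0.0, 0.0, 1.0]), id=2),
    ]
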