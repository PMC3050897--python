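"""Error signal, reward sign and the ARP weight update.

The associative reward-penalty (ARP) rule shares one scalar error
across the whole network: the normalized Euclidean distance ``d``
between the output activity and the current target selects a reward
sign ``delta`` (+1 when ``d < eps_d``, else -1), and every plastic
synapse ``J[post, pre]`` changes as

    dJ/dt = (1 / tau_syn) * delta * (x_post - r0) * g(x_pre)

with ``tau_syn = tau_f`` for the two forward matrices and ``tau_b`` for
the backward matrix, and a presynaptic gate ``g`` with ``g(0) = 0`` so
that synapses from low-firing neurons barely change.  ``delta = +1``
is Hebbian (stabilizes the ongoing pattern), ``delta = -1``
anti-Hebbian (destabilizes it, driving the itinerant search).  As in
the classic reward-penalty algorithm the two signs use asymmetric
learning rates: penalty updates are scaled by ``lambda_penalty <= 1``,
so the destabilizing search perturbs consolidated weights only weakly.
Weights are clipped to ``[0, w_max]``: synapses are excitatory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import NetworkState, SynapticWeights
from .params import NetworkParams

__all__ = [
    "ErrorSignal",
    "error_distance",
    "reward_signal",
    "presynaptic_gate",
    "update_weights",
]


@dataclass(frozen=True)
class ErrorSignal:
    """Scalar error ``d`` and the reward sign ``delta`` derived from it."""

    d: float
    delta: int

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.delta not in (+1, -1):
            raise ValueError("delta must be +1 or -1")


def error_distance(output: np.ndarray, target: np.ndarray) -> float:
    """Normalized Euclidean distance ``||output - target|| / ||target||``.

    Zero exactly when the output equals the target.
    """
    output = np.asarray(output, dtype=float)
    target = np.asarray(target, dtype=float)
    if output.shape != target.shape:
        raise ValueError(
            f"output shape {output.shape} != target shape {target.shape}"
        )
    tnorm = np.linalg.norm(target)
    if tnorm == 0:
        raise ValueError("target must not be the zero vector")
    return float(np.linalg.norm(output - target) / tnorm)


def reward_signal(d: float, params: NetworkParams) -> int:
    """Reward sign: +1 (Hebbian) iff ``d < eps_d``, else -1 (anti-Hebbian).

    The tie ``d == eps_d`` counts as distant (-1).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    return +1 if d < params.eps_d else -1


def presynaptic_gate(x_pre):
    """Gate ``g`` suppressing plasticity of synapses from quiet neurons.

    The identity ``g(x) = x`` — zero at zero, nondecreasing — is the
    minimal form with the required behavior.
    """
    return np.asarray(x_pre, dtype=float) if np.ndim(x_pre) else float(x_pre)


def update_weights(
    w: SynapticWeights,
    state: NetworkState,
    input: np.ndarray | None,
    gamma: float,
    delta: int,
    params: NetworkParams,
    dt: float | None = None,
) -> SynapticWeights:
    """One Euler step of the ARP weight update; returns new weights.

    Each plastic entry is incremented by
    ``dt / tau_syn * delta * (x_post - r0) * g(x_pre)`` and clipped to
    ``[0, w_max]``.  The presynaptic rate for the input->hidden matrix
    is the clamped input-layer activity ``gamma * xi`` (zero when no
    input is applied, so that matrix is then untouched).  Inhibitory
    strengths are a fixed scalar and never change.
    """
    if delta not in (+1, -1):
        raise ValueError("delta must be +1 or -1")
    if dt is None:
        dt = params.dt
    dt = dt * (1.0 if delta > 0 else params.lambda_penalty)
    dt_f = dt
    xh, xo = state.x_hidden, state.x_output
    r0, wm = params.r0, params.w_max
    if input is None:
        x_in = np.zeros(params.N_in)
    else:
        x_in = gamma * np.asarray(input, dtype=float)
    g = presynaptic_gate
    J_ih = w.J_ih + (dt_f / params.tau_f) * delta * np.outer(xh - r0, g(x_in))
    J_ho = w.J_ho + (dt_f / params.tau_f) * delta * np.outer(xo - r0, g(xh))
    J_oh = w.J_oh + (dt / params.tau_b) * delta * np.outer(xh - r0, g(xo))
    return SynapticWeights(
        np.clip(J_ih, 0.0, wm), np.clip(J_ho, 0.0, wm), np.clip(J_oh, 0.0, wm)
    )
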