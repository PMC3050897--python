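"""Rate dynamics of the hidden and output layers.

The three-layer network consists of an input layer clamped at
``gamma * xi`` (a boundary condition, never integrated), and hidden and
output layers of rate-coding neurons obeying leaky relaxation

    tau * dx_i/dt = -x_i + f(I_i),      f(u) = 1 / (1 + exp(-beta (u - theta)))

where the current ``I_i`` sums excitatory forward drive (input->hidden,
hidden->output), excitatory backward drive (output->hidden) and the
mutually inhibitory intralayer coupling ``c_inh * sum_{j != i} x_j``
within each of the two integrated layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import NetworkParams

__all__ = [
    "NetworkState",
    "SynapticWeights",
    "Trajectory",
    "IntegrationInstabilityError",
    "activation",
    "input_currents",
    "step_dynamics",
    "simulate",
    "random_state",
]


class IntegrationInstabilityError(RuntimeError):
    """A firing rate left [0, 1]; the integration step is too large."""


# --------------------------------------------------------------------
# containers
# --------------------------------------------------------------------
@dataclass
class NetworkState:
    """Firing rates of the hidden and output layers at time ``t``."""

    x_hidden: np.ndarray
    x_output: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x_hidden = np.asarray(self.x_hidden, dtype=float)
        self.x_output = np.asarray(self.x_output, dtype=float)
        for x in (self.x_hidden, self.x_output):
            if not np.all(np.isfinite(x)):
                raise ValueError("rates must be finite")
            if np.any(x <= 0) or np.any(x >= 1):
                raise ValueError("rates must lie strictly in (0, 1)")

    def copy(self) -> "NetworkState":
        return NetworkState(self.x_hidden.copy(), self.x_output.copy(), self.t)

    @property
    def concatenated(self) -> np.ndarray:
        """Hidden and output rates as a single vector."""
        return np.concatenate([self.x_hidden, self.x_output])


@dataclass
class SynapticWeights:
    """The three plastic, excitatory weight matrices.

    ``J_ih`` (hidden x input) and ``J_ho`` (output x hidden) are forward
    synapses sharing the slow plasticity timescale ``tau_f``; ``J_oh``
    (hidden x output) are backward synapses on the faster ``tau_b``.
    Inhibitory intralayer strengths are a fixed scalar (``c_inh``) and
    are not stored.  Entry ``J[post, pre]``; all entries nonnegative.
    """

    J_ih: np.ndarray
    J_ho: np.ndarray
    J_oh: np.ndarray

    def __post_init__(self) -> None:
        self.J_ih = np.ascontiguousarray(self.J_ih, dtype=float)
        self.J_ho = np.ascontiguousarray(self.J_ho, dtype=float)
        self.J_oh = np.ascontiguousarray(self.J_oh, dtype=float)
        for name, J in self.items():
            if not np.all(np.isfinite(J)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(J < 0):
                raise ValueError(f"{name} contains negative entries")

    def items(self):
        return [("J_ih", self.J_ih), ("J_ho", self.J_ho), ("J_oh", self.J_oh)]

    def copy(self) -> "SynapticWeights":
        return SynapticWeights(self.J_ih.copy(), self.J_ho.copy(), self.J_oh.copy())

    @classmethod
    def zeros(cls, params: NetworkParams) -> "SynapticWeights":
        return cls(
            np.zeros((params.N_hid, params.N_in)),
            np.zeros((params.N_out, params.N_hid)),
            np.zeros((params.N_hid, params.N_out)),
        )

    @classmethod
    def uniform(
        cls, params: NetworkParams, rng: np.random.Generator
    ) -> "SynapticWeights":
        """Uniform(0, 1) initial strengths for every plastic synapse."""
        return cls(
            rng.uniform(0, 1, (params.N_hid, params.N_in)),
            rng.uniform(0, 1, (params.N_out, params.N_hid)),
            rng.uniform(0, 1, (params.N_hid, params.N_out)),
        )

    def check_shapes(self, params: NetworkParams) -> None:
        expect = {
            "J_ih": (params.N_hid, params.N_in),
            "J_ho": (params.N_out, params.N_hid),
            "J_oh": (params.N_hid, params.N_out),
        }
        for name, J in self.items():
            if J.shape != expect[name]:
                raise ValueError(
                    f"{name} has shape {J.shape}, expected {expect[name]}"
                )


@dataclass
class Trajectory:
    """Recorded snapshots of a simulation run."""

    times: np.ndarray
    hidden: np.ndarray  # (T, N_hid)
    output: np.ndarray  # (T, N_out)
    input_applied: np.ndarray | None = None
    gamma: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.hidden) or len(self.times) != len(self.output):
            raise ValueError("snapshot count must equal time count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def final_state(self) -> NetworkState:
        return NetworkState(self.hidden[-1], self.output[-1], float(self.times[-1]))

    def to_frame(self):
        """Trajectory as a pandas DataFrame (t, h_0.., o_0..)."""
        import pandas as pd

        cols = {"t": self.times}
        for i in range(self.hidden.shape[1]):
            cols[f"h_{i}"] = self.hidden[:, i]
        for i in range(self.output.shape[1]):
            cols[f"o_{i}"] = self.output[:, i]
        return pd.DataFrame(cols)


def random_state(
    params: NetworkParams, rng: np.random.Generator, t: float = 0.0
) -> NetworkState:
    """Random initial rates drawn uniformly in (0, 1)."""
    lo, hi = 1e-6, 1 - 1e-6
    return NetworkState(
        rng.uniform(lo, hi, params.N_hid), rng.uniform(lo, hi, params.N_out), t
    )


# --------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------
def activation(u, params: NetworkParams):
    """Logistic rate function ``1 / (1 + exp(-beta (u - theta)))``.

    Strictly increasing, with values in (0, 1); ``activation(theta)`` is
    exactly 0.5 and, with the default threshold, ``activation(0)``
    equals the spontaneous rate ``r0``.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("current must be finite")
    with np.errstate(over="ignore"):  # saturated tails are exactly 0 or 1
        out = 1.0 / (1.0 + np.exp(-params.beta * (u - params.theta)))
    return float(out) if out.ndim == 0 else out


def input_currents(
    state: NetworkState,
    w: SynapticWeights,
    input: np.ndarray | None,
    gamma: float,
    params: NetworkParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Total current into each hidden and output neuron.

    Hidden neurons receive forward drive ``gamma * J_ih @ xi`` from the
    clamped input layer (absent when ``input`` is None — spontaneous
    condition), backward drive ``J_oh @ x_output``, and intralayer
    inhibition; output neurons receive ``J_ho @ x_hidden`` plus
    inhibition.  Self-inhibition is excluded.
    """
    w.check_shapes(params)
    if state.x_hidden.size != params.N_hid or state.x_output.size != params.N_out:
        raise ValueError("state size inconsistent with params")
    xh, xo = state.x_hidden, state.x_output
    I_h = w.J_oh @ xo + params.c_inh * (xh.sum() - xh)
    if input is not None:
        xi = np.asarray(input, dtype=float)
        if xi.size != params.N_in:
            raise ValueError(
                f"input pattern length {xi.size} != N_in {params.N_in}"
            )
        I_h = I_h + gamma * (w.J_ih @ xi)
    I_o = w.J_ho @ xh + params.c_inh * (xo.sum() - xo)
    return I_h, I_o


def step_dynamics(
    state: NetworkState,
    w: SynapticWeights,
    input: np.ndarray | None,
    gamma: float,
    params: NetworkParams,
) -> NetworkState:
    """One explicit-Euler step of the rate dynamics.

    With ``dt <= tau`` the update is a convex combination of the old
    rate and an activation value in (0, 1), so rates stay in (0, 1).
    """
    I_h, I_o = input_currents(state, w, input, gamma, params)
    a = params.dt / params.tau
    xh = state.x_hidden + a * (-state.x_hidden + activation(I_h, params))
    xo = state.x_output + a * (-state.x_output + activation(I_o, params))
    for x in (xh, xo):
        if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
            raise IntegrationInstabilityError(
                "a rate left [0, 1]; reduce the integration step dt"
            )
    return NetworkState(xh, xo, state.t + params.dt)


def simulate(
    state0: NetworkState,
    w: SynapticWeights,
    input: np.ndarray | None,
    gamma: float,
    T: float,
    params: NetworkParams,
    record_every: int = 1,
) -> Trajectory:
    """Integrate the frozen-weight dynamics for duration ``T``.

    Deterministic given ``(state0, w, input, gamma, params)``.  Every
    ``record_every``-th step is recorded, and the final state always is.
    ``T = 0`` yields a trajectory holding only the initial snapshot.
    """
    if T < 0:
        raise ValueError("duration T must be >= 0")
    w.check_shapes(params)
    n_steps = int(round(T / params.dt))
    if n_steps == 0:
        return Trajectory(
            np.array([state0.t]),
            state0.x_hidden[None, :].copy(),
            state0.x_output[None, :].copy(),
            None if input is None else np.asarray(input, float),
            gamma,
        )
    # explicit copies: the kernel advances these buffers in place and the
    # caller's state must stay untouched
    Xh = state0.x_hidden.astype(float).reshape(-1, 1).copy()
    Xo = state0.x_output.astype(float).reshape(-1, 1).copy()
    if input is not None:
        xi = np.asarray(input, dtype=float)
        if xi.size != params.N_in:
            raise ValueError("input pattern length inconsistent with params")
        I_ext = np.ascontiguousarray((gamma * (w.J_ih @ xi))[:, None])
    else:
        I_ext = np.zeros((params.N_hid, 1))
    n_frames = n_steps // record_every + 2
    rec_h = np.empty((n_frames, params.N_hid, 1))
    rec_o = np.empty((n_frames, params.N_out, 1))
    steps, n_rec = _kernels.relax(
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
        n_steps,
        0.0,
        record_every,
        rec_h,
        rec_o,
    )
    times = list(state0.t + params.dt * record_every * np.arange(n_rec))
    hidden = list(rec_h[:n_rec, :, 0])
    output = list(rec_o[:n_rec, :, 0])
    t_end = state0.t + params.dt * steps
    if not times or times[-1] < t_end:
        times.append(t_end)
        hidden.append(Xh[:, 0].copy())
        output.append(Xo[:, 0].copy())
    traj = Trajectory(
        np.array(times),
        np.array(hidden),
        np.array(output),
        None if input is None else np.asarray(input, float),
        gamma,
    )
    if np.any(traj.hidden < -1e-9) or np.any(traj.hidden > 1 + 1e-9):
        raise IntegrationInstabilityError(
            "a rate left [0, 1]; reduce the integration step dt"
        )
    return traj
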