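"""Scalar constants of the network dynamics and plasticity.

All times are expressed in units of the neural time constant ``tau``
(default 1.0).  The three timescales of the model are ``tau`` (neural
activity), ``tau_b`` (backward-synapse plasticity) and ``tau_f``
(forward-synapse plasticity); sequential learning requires
``tau << tau_b << tau_f``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

__all__ = ["NetworkParams", "load_config", "dump_config"]


@dataclass(frozen=True)
class NetworkParams:
    """All scalar constants of the rate dynamics and the plasticity rule.

    Parameters
    ----------
    N : int
        Neurons per layer (input, hidden and output layers are all size
        ``N`` unless the per-layer overrides below are given).
    tau : float
        Time constant of the firing-rate relaxation.
    beta : float
        Gain (steepness) of the logistic activation.  Winner-take-all
        competition through the inhibitory intralayer synapses requires
        ``beta * r0 * (1 - r0) > 1`` so that the symmetric
        equal-activity state is unstable.
    theta : float or None
        Activation threshold.  ``None`` (default) selects the threshold
        such that the activation of a zero current equals the
        spontaneous rate ``r0``, i.e. ``theta = log(1/r0 - 1) / beta``.
    c_inh : float
        Strength of the mutually inhibitory intralayer synapses
        (identical for all pairs, zero for self-connections).
    gamma_learn : float
        Input strength applied while learning and during recall tests.
    dt : float
        Explicit-Euler integration step.  Must satisfy ``dt <= tau/10``.
    r0 : float
        Spontaneous firing rate entering the postsynaptic plasticity
        factor ``(x_post - r0)``.
    eps_d : float
        Error threshold: output-target distance ``d < eps_d`` switches
        the plasticity from anti-Hebbian (search) to Hebbian
        (stabilization).
    lambda_penalty : float
        Learning-rate asymmetry of the associative reward-penalty rule:
        anti-Hebbian (penalty) updates are scaled by this factor
        relative to Hebbian (reward) updates.  Values well below 1 make
        the itinerant search gentle on previously stored forward
        weights while leaving consolidation at full rate.
    tau_f, tau_b : float
        Plasticity time constants of the forward synapses (input->hidden
        and hidden->output) and of the backward synapses
        (output->hidden).
    w_max : float
        Upper bound on every plastic synaptic strength (``inf`` unless a
        bounded-weight task, e.g. the overlapping-input task, is run).
    n_input, n_hidden, n_output : int or None
        Per-layer sizes; ``None`` means ``N``.  Unequal sizes are only
        needed for the overlapping-input extension task.
    """

    N: int = 16
    tau: float = 1.0
    beta: float = 100.0
    theta: float | None = None
    c_inh: float = -1.0
    gamma_learn: float = 2.0
    dt: float = 0.01
    r0: float = 0.1
    eps_d: float = 0.5
    lambda_penalty: float = 0.1
    tau_f: float = 100.0
    tau_b: float = 10.0
    w_max: float = math.inf
    n_input: int | None = None
    n_hidden: int | None = None
    n_output: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        for name in ("tau", "dt", "tau_f", "tau_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dt > self.tau / 10 + 1e-12:
            raise ValueError(
                f"dt={self.dt} too large for tau={self.tau}; need dt <= tau/10"
            )
        if not 0 < self.r0 < 1:
            raise ValueError(f"r0 must lie in (0, 1), got {self.r0}")
        if not 0 < self.eps_d < 1:
            raise ValueError(f"eps_d must lie in (0, 1), got {self.eps_d}")
        if not 0 < self.lambda_penalty <= 1:
            raise ValueError(
                f"lambda_penalty must lie in (0, 1], got {self.lambda_penalty}"
            )
        if self.c_inh > 0:
            raise ValueError(f"c_inh must be <= 0, got {self.c_inh}")
        if self.w_max <= 0:
            raise ValueError(f"w_max must be > 0, got {self.w_max}")
        if self.theta is None:
            object.__setattr__(
                self, "theta", math.log(1.0 / self.r0 - 1.0) / self.beta
            )
        for name in ("n_input", "n_hidden", "n_output"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")

    # -- layer sizes -------------------------------------------------
    @property
    def N_in(self) -> int:
        return self.n_input if self.n_input is not None else self.N

    @property
    def N_hid(self) -> int:
        return self.n_hidden if self.n_hidden is not None else self.N

    @property
    def N_out(self) -> int:
        return self.n_output if self.n_output is not None else self.N

    def replace(self, **kwargs: Any) -> "NetworkParams":
        """Return a copy with some fields replaced."""
        d = dataclasses.asdict(self)
        # theta was resolved in __post_init__; keep it unless beta or r0
        # change, in which case it is re-derived.
        if ("beta" in kwargs or "r0" in kwargs) and "theta" not in kwargs:
            d["theta"] = None
        d.update(kwargs)
        return NetworkParams(**d)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if math.isinf(d["w_max"]):
            d["w_max"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NetworkParams":
        d = dict(d)
        if isinstance(d.get("w_max"), str):
            d["w_max"] = float(d["w_max"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a TOML or YAML experiment configuration.

    The file may hold NetworkParams keys at top level or under a
    ``[network]`` table, plus arbitrary protocol keys (seeds, durations,
    thresholds) that callers interpret.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        import tomllib

        data = tomllib.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root of {path} is not a mapping")
    return data


def dump_config(data: dict[str, Any], path: str | Path) -> None:
    """Write a configuration mapping as YAML (human-diffable)."""
    import yaml

    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def params_from_config(data: dict[str, Any]) -> NetworkParams:
    """Build NetworkParams from a config mapping.

    Accepts either a flat mapping restricted to known keys or a mapping
    with a ``network`` sub-table.
    """
    if "network" in data and isinstance(data["network"], dict):
        return NetworkParams.from_dict(data["network"])
    known = {f.name for f in dataclasses.fields(NetworkParams)}
    return NetworkParams.from_dict({k: v for k, v in data.items() if k in known})
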