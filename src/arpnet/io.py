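"""Serialization of weights, runs and configurations.

Array-heavy artifacts (weight snapshots, learning traces) go into one
HDF5 container per run with the full configuration embedded as a JSON
attribute for provenance; tabular summaries (capacity curves, censuses,
phase grids) are exported as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .dynamics import SynapticWeights
from .params import NetworkParams
from .protocol import CapacityCurve, CurriculumResult, LearningTrace

__all__ = [
    "SchemaError",
    "save_weights",
    "load_weights",
    "save_run",
    "load_run",
    "capacity_frame",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """The file does not match the expected run/weights schema."""


def _write_weights(group: h5py.Group, w: SynapticWeights) -> None:
    for name, J in w.items():
        group.create_dataset(name, data=J)


def _read_weights(group: h5py.Group) -> SynapticWeights:
    missing = [k for k in ("J_ih", "J_ho", "J_oh") if k not in group]
    if missing:
        raise SchemaError(f"weight group {group.name} missing {missing}")
    return SynapticWeights(
        group["J_ih"][()], group["J_ho"][()], group["J_oh"][()]
    )


def save_weights(path: str | Path, w: SynapticWeights,
                 params: NetworkParams | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "weights"
        if params is not None:
            f.attrs["params"] = json.dumps(params.to_dict())
        _write_weights(f.create_group("weights"), w)


def load_weights(path: str | Path) -> tuple[SynapticWeights, NetworkParams | None]:
    with h5py.File(path, "r") as f:
        _check_schema(f, "weights")
        w = _read_weights(f["weights"])
        params = None
        if "params" in f.attrs:
            params = NetworkParams.from_dict(json.loads(f.attrs["params"]))
    return w, params


def _check_schema(f: h5py.File, kind: str) -> None:
    if f.attrs.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version {f.attrs.get('schema_version')!r} != {SCHEMA_VERSION}"
        )
    if f.attrs.get("kind") != kind:
        raise SchemaError(f"file kind {f.attrs.get('kind')!r}, expected {kind!r}")


def save_run(path: str | Path, result: CurriculumResult,
             extra_config: dict | None = None) -> None:
    """Write a curriculum run (weights history, traces, counts) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "run"
        f.attrs["seed"] = result.seed
        f.attrs["params"] = json.dumps(result.params.to_dict())
        if extra_config:
            f.attrs["config"] = json.dumps(extra_config)
        f.create_dataset("capacity/counts", data=np.asarray(result.capacity_curve.counts))
        f.create_dataset(
            "statuses", data=np.array(result.statuses, dtype=h5py.string_dtype())
        )
        for k, w in enumerate(result.weight_history):
            _write_weights(f.create_group(f"weights/step_{k:03d}"), w)
        for k, frac in enumerate(result.fractions):
            f.create_dataset(f"fractions/step_{k:03d}", data=frac)
        for k, tr in enumerate(result.traces):
            g = f.create_group(f"traces/step_{k:03d}")
            g.create_dataset("times", data=tr.times)
            g.create_dataset("d", data=tr.d_series)
            g.create_dataset("phase", data=tr.phase_series)
            g.create_dataset("output", data=tr.output)
            g.attrs["mapping_id"] = tr.mapping_id
            g.attrs["success"] = tr.success
            g.attrs["duration"] = tr.duration


def load_run(path: str | Path) -> CurriculumResult:
    """Read a curriculum run; bit-exact for integers, full float precision."""
    with h5py.File(path, "r") as f:
        _check_schema(f, "run")
        params = NetworkParams.from_dict(json.loads(f.attrs["params"]))
        counts = [int(c) for c in f["capacity/counts"][()]]
        statuses = [s.decode() for s in f["statuses"][()]]
        n_steps = len(counts)
        weights, fractions, traces = [], [], []
        for k in range(n_steps):
            weights.append(_read_weights(f[f"weights/step_{k:03d}"]))
            fractions.append(f[f"fractions/step_{k:03d}"][()])
            tkey = f"traces/step_{k:03d}"
            if tkey in f:
                g = f[tkey]
                traces.append(
                    LearningTrace(
                        g["times"][()], g["d"][()], g["phase"][()], g["output"][()],
                        int(g.attrs["mapping_id"]), bool(g.attrs["success"]),
                        float(g.attrs["duration"]),
                    )
                )
        return CurriculumResult(
            CapacityCurve(counts), weights, traces, statuses, fractions,
            params, int(f.attrs["seed"]),
        )


def capacity_frame(result: CurriculumResult):
    """Capacity curve as a pandas DataFrame (step, memorized, capacity)."""
    import pandas as pd

    counts = result.capacity_curve.counts
    return pd.DataFrame(
        {
            "step": np.arange(1, len(counts) + 1),
            "memorized": counts,
            "capacity": np.maximum.accumulate(counts),
            "status": result.statuses,
        }
    )
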