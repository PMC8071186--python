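"""Output writers: receiver-trace CSV, field snapshots, run summaries.

Snapshots are written as flat little-endian 64-bit floats in row-major
(r-major) order with a JSON sidecar recording the array shape, grid steps,
wall radius and snapshot time; the round-trip through
:func:`write_snapshot` / :func:`read_snapshot` is bit exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec
from .solver import SimulationResult

__all__ = ["write_traces_csv", "write_snapshot", "read_snapshot", "write_summary"]


def write_traces_csv(result: SimulationResult, path) -> None:
    """Write receiver traces: column 1 time (s), one column per receiver.

    The header names each receiver by its wall position.
    """
    cols = {"time_s": result.times}
    for k, label in enumerate(result.probe_labels):
        cols[label or f"probe_{k}"] = result.traces[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_snapshot(field: np.ndarray, grid: GridSpec, time: float, path) -> None:
    """Write one 2-D displacement snapshot as flat f64 + JSON sidecar."""
    path = Path(path)
    arr = np.ascontiguousarray(field, dtype="<f8")
    arr.tofile(path)
    sidecar = {
        "shape": list(arr.shape),
        "dtype": "<f8",
        "order": "row-major (r index varies slowest)",
        "dr_m": grid.dr,
        "dz_m": grid.dz,
        "r0_m": grid.r0,
        "n_pml": grid.n_pml,
        "time_s": time,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1) + "\n"
    )


def read_snapshot(path) -> tuple[np.ndarray, dict]:
    """Read a snapshot written by :func:`write_snapshot` (bit exact)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    return arr, meta


def write_summary(metrics: dict, path) -> None:
    """Write a JSON summary of run/study metrics."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(metrics, indent=1, default=_default) + "\n")
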