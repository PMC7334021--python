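"""Readers/writers for the package's text artifact formats.

Traces are CSV (``time_ms,<site>...``, one row per step) with a JSON
sidecar (same path + ``.json``) holding dt, sites, stimulus provenance and
the configuration digest. Sweep grids are long-format CSV
(``axis1,axis2,value``). Cohort tables are plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cable import Trace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_sweep_csv",
    "read_sweep_csv",
]


def write_trace_csv(trace: Trace, path) -> Path:
    """Write a Trace to CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    cols = {"time_ms": trace.time}
    for s in trace.sites:
        cols[s] = trace.values[s]
    for name, cur in trace.currents.items():
        cols[f"i_{name}_nA"] = cur
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "dt": trace.dt,
        "duration": trace.duration,
        "sites": trace.sites,
        "currents": list(trace.currents),
        "meta": trace.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, default=str)
    )
    return path


def read_trace_csv(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = {s: df[s].to_numpy() for s in side["sites"]}
    currents = {
        name: df[f"i_{name}_nA"].to_numpy() for name in side.get("currents", [])
    }
    return Trace(
        dt=side["dt"],
        duration=side["duration"],
        sites=side["sites"],
        values=values,
        currents=currents,
        meta=side.get("meta", {}),
    )


def write_sweep_csv(grid, path) -> Path:
    """Long-format CSV: axis1,axis2,value."""
    path = Path(path)
    rows = []
    for i, a in enumerate(grid.axis1):
        for j, b in enumerate(grid.axis2):
            rows.append((a, b, grid.values[i, j]))
    df = pd.DataFrame(rows, columns=[grid.axis1_name, grid.axis2_name, "value"])
    df.to_csv(path, index=False, float_format="%.9g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(grid.meta, indent=1, default=str)
    )
    return path


def read_sweep_csv(path):
    from .protocols import SweepGrid

    path = Path(path)
    df = pd.read_csv(path)
    a1, a2, _ = df.columns
    axis1 = np.unique(df[a1])
    axis2 = np.unique(df[a2])
    vals = (
        df.pivot(index=a1, columns=a2, values="value")
        .loc[axis1, axis2]
        .to_numpy()
    )
    meta = {}
    sc = path.with_suffix(path.suffix + ".json")
    if sc.exists():
        meta = json.loads(sc.read_text())
    return SweepGrid(a1, axis1, a2, axis2, vals, meta=meta)
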