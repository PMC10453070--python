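"""Snapshot and table output.

Three formats: legacy-ASCII structured-points VTK (readable by ParaView and
friends), columnar CSV (one row per cell centre), and a binary array bundle
(NumPy ``.npz``) that round-trips bit-identically.  Scalars are written at
cell centres; the velocity is interpolated to centres and written as a
vector field.  Every writer embeds the run metadata (time, step, scheme
switches) so an output directory is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec, velocity_to_centers

__all__ = ["write_snapshot", "write_vtk", "write_csv", "write_bundle",
           "read_bundle", "write_metadata"]


def _center_fields(snapshot: dict, grid: GridSpec) -> dict:
    fields = {k: snapshot[k] for k in ("q", "c", "p") if k in snapshot}
    if "v1" in snapshot and "v2" in snapshot:
        v1c, v2c = velocity_to_centers(snapshot["v1"], snapshot["v2"])
        fields["u"] = (v1c, v2c)
    return fields


def write_vtk(path, grid: GridSpec, snapshot: dict, meta: dict | None = None):
    """Legacy-ASCII VTK structured points: dimensions (Nx, Ny, 1), origin at
    the first cell centre, spacing (hx, hy, 1)."""
    path = Path(path)
    fields = _center_fields(snapshot, grid)
    lines = [
        "# vtk DataFile Version 3.0",
        f"chemoflow snapshot t={snapshot.get('t', 0.0):.8g} "
        f"step={snapshot.get('step', 0)}",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {grid.Nx} {grid.Ny} 1",
        f"ORIGIN {grid.xc[0]:.12g} {grid.yc[0]:.12g} 0",
        f"SPACING {grid.hx:.12g} {grid.hy:.12g} 1",
        f"POINT_DATA {grid.Nx * grid.Ny}",
    ]
    for name, val in fields.items():
        if name == "u":
            v1c, v2c = val
            lines.append(f"VECTORS {name} double")
            # VTK structured order: x fastest
            for j in range(grid.Ny):
                for i in range(grid.Nx):
                    lines.append(f"{v1c[i, j]:.10g} {v2c[i, j]:.10g} 0")
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            for j in range(grid.Ny):
                lines.append(" ".join(f"{val[i, j]:.10g}"
                                      for i in range(grid.Nx)))
    path.write_text("\n".join(lines) + "\n")
    if meta:
        write_metadata(path.with_suffix(".meta.json"), meta, snapshot)
    return path


def write_csv(path, grid: GridSpec, snapshot: dict, meta: dict | None = None):
    """Columnar CSV: one row per cell centre (x, y, q, c, p, u1, u2)."""
    path = Path(path)
    fields = _center_fields(snapshot, grid)
    X, Y = np.meshgrid(grid.xc, grid.yc, indexing="ij")
    cols = {"x": X.ravel(), "y": Y.ravel()}
    for name, val in fields.items():
        if name == "u":
            cols["u1"] = val[0].ravel()
            cols["u2"] = val[1].ravel()
        else:
            cols[name] = val.ravel()
    pd.DataFrame(cols).to_csv(path, index=False)
    if meta:
        write_metadata(path.with_suffix(".meta.json"), meta, snapshot)
    return path


def write_bundle(path, grid: GridSpec, snapshot: dict,
                 meta: dict | None = None):
    """Binary bundle (.npz) carrying the raw staggered arrays; reading it
    back returns bit-identical fields."""
    path = Path(path)
    arrays = {k: v for k, v in snapshot.items()
              if isinstance(v, np.ndarray)}
    arrays["xc"] = grid.xc
    arrays["yc"] = grid.yc
    header = {"t": snapshot.get("t", 0.0), "step": snapshot.get("step", 0)}
    if meta:
        header["meta"] = meta
    np.savez(path, __meta__=json.dumps(header), **arrays)
    return path


def read_bundle(path):
    """Read a bundle back: (fields dict, metadata dict)."""
    with np.load(path, allow_pickle=False) as z:
        fields = {k: z[k] for k in z.files if k != "__meta__"}
        meta = json.loads(str(z["__meta__"]))
    return fields, meta


def write_snapshot(path, grid: GridSpec, snapshot: dict, fmt: str = "vtk",
                   meta: dict | None = None):
    """Dispatch on format: 'vtk' | 'csv' | 'bundle'."""
    writers = {"vtk": write_vtk, "csv": write_csv, "bundle": write_bundle}
    if fmt not in writers:
        raise ValueError(f"unknown snapshot format {fmt!r}")
    try:
        return writers[fmt](path, grid, snapshot, meta=meta)
    except OSError as e:
        raise OSError(f"failed writing snapshot to {path}: {e}") from e


def write_metadata(path, meta: dict, snapshot: dict | None = None):
    payload = dict(meta)
    if snapshot is not None:
        payload["t"] = snapshot.get("t")
        payload["step"] = snapshot.get("step")
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
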