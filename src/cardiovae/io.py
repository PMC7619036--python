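"""Readers and writers for the package's on-disk formats.

Labeled point clouds travel as ASCII PLY (with an integer ``label`` vertex
property) or plain-text XYZL (four whitespace-separated columns); both
round-trip losslessly to well below 1e-6 mm.  Tetrahedral meshes are written
as legacy-ASCII VTK unstructured grids with cell-data fiber vectors and
point-data activation times; ECG traces and cohort metadata as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_anatomy import MultiClassPointCloud

__all__ = [
    "write_xyzl", "read_xyzl", "write_ply", "read_ply",
    "write_vtk_tetmesh", "write_ecg_csv", "read_ecg_csv",
]

_FMT = "%.8g"  # lossless for mm-scale coordinates at float32 precision


def write_xyzl(path, cloud: MultiClassPointCloud) -> None:
    """Write a labeled cloud as 4 whitespace-separated columns (x y z label)."""
    data = np.column_stack([cloud.points, cloud.labels.astype(float)])
    np.savetxt(path, data, fmt=[_FMT, _FMT, _FMT, "%d"])


def read_xyzl(path, phase: str = "ED") -> MultiClassPointCloud:
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 4:
        raise ValueError(f"XYZL file must have 4 columns, got {data.shape[1]}")
    return MultiClassPointCloud(
        points=data[:, :3], labels=data[:, 3].astype(int), phase=phase
    )


def write_ply(path, cloud: MultiClassPointCloud) -> None:
    """ASCII PLY point cloud with an integer ``label`` vertex property."""
    n = cloud.points.shape[0]
    header = "\n".join([
        "ply", "format ascii 1.0",
        f"comment phase {cloud.phase}",
        f"element vertex {n}",
        "property double x", "property double y", "property double z",
        "property int label",
        "end_header",
    ])
    lines = [header]
    for (x, y, z), lab in zip(cloud.points, cloud.labels):
        lines.append(f"{x:.8g} {y:.8g} {z:.8g} {int(lab)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ply(path, phase: str | None = None) -> MultiClassPointCloud:
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise ValueError(f"{path} is not a PLY file")
    n = None
    props: list[str] = []
    file_phase = "ED"
    i = 0
    for i, line in enumerate(text):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "comment" and len(tok) >= 3 and tok[1] == "phase":
            file_phase = tok[2]
        elif tok[0] == "element" and tok[1] == "vertex":
            n = int(tok[2])
        elif tok[0] == "property" and n is not None:
            props.append(tok[-1])
        elif tok[0] == "end_header":
            break
    if n is None:
        raise ValueError(f"{path}: missing vertex element")
    for need in ("x", "y", "z", "label"):
        if need not in props:
            raise ValueError(f"{path}: missing vertex property {need!r}")
    cols = {p: j for j, p in enumerate(props)}
    body = np.array(
        [[float(v) for v in line.split()] for line in text[i + 1: i + 1 + n]]
    )
    return MultiClassPointCloud(
        points=body[:, [cols["x"], cols["y"], cols["z"]]],
        labels=body[:, cols["label"]].astype(int),
        phase=phase or file_phase,
    )


def write_vtk_tetmesh(path, mesh, activation=None) -> None:
    """Legacy-ASCII VTK unstructured grid for a tetrahedral mesh.

    Writes points, tetra cells, per-cell fiber/sheet/normal vectors when the
    mesh carries fiber frames, and per-point activation times when given.
    """
    nodes = np.asarray(mesh.nodes)
    tets = np.asarray(mesh.tets)
    out = [
        "# vtk DataFile Version 3.0",
        "cardiovae biventricular tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    out += [f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}" for p in nodes]
    out.append(f"CELLS {len(tets)} {5 * len(tets)}")
    out += ["4 " + " ".join(str(int(v)) for v in t) for t in tets]
    out.append(f"CELL_TYPES {len(tets)}")
    out += ["10"] * len(tets)
    if getattr(mesh, "fibers", None) is not None:
        out.append(f"CELL_DATA {len(tets)}")
        for name, vecs in (("fiber", mesh.fibers), ("sheet", mesh.sheets),
                           ("normal", mesh.normals)):
            out.append(f"VECTORS {name} double")
            out += [f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}" for v in vecs]
    if activation is not None:
        act = np.asarray(activation, dtype=float)
        out += [f"POINT_DATA {len(nodes)}", "SCALARS activation_ms double 1",
                "LOOKUP_TABLE default"]
        out += [f"{t:.8g}" for t in act]
    Path(path).write_text("\n".join(out) + "\n")


def write_ecg_csv(path, trace) -> None:
    """ECG trace as CSV with columns time_ms, I, II, V1..V6."""
    df = pd.DataFrame({"time_ms": trace.times})
    for name, sig in zip(trace.lead_names, trace.leads):
        df[name] = sig
    df.to_csv(path, index=False)


def read_ecg_csv(path):
    from .ep_pipeline import ECGTrace

    df = pd.read_csv(path)
    names = [c for c in df.columns if c != "time_ms"]
    return ECGTrace(
        times=df["time_ms"].to_numpy(float),
        leads=np.array([df[c].to_numpy(float) for c in names]),
        lead_names=tuple(names),
    )
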