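"""Legacy-ASCII VTK writers for the tissue grid and the vascular polyline
network, plus the combined snapshot writer.  Output is bit-stable for
identical state (fixed %.17g formatting)."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .mesh import Mesh
from .network import VascularNetwork, write_segment_csv


def _fmt(x):
    return f"{float(x):.17g}"


def write_vtk_unstructured(path, nodes: np.ndarray, elems: np.ndarray,
                           point_data: Optional[dict] = None) -> None:
    """Hexahedral unstructured grid with optional scalar/vector point data."""
    nodes = np.asarray(nodes, dtype=float)
    elems = np.asarray(elems, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmechangio tissue state\n"
                 "ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for p in nodes:
            fh.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        fh.write(f"CELLS {len(elems)} {len(elems) * 9}\n")
        for e in elems:
            fh.write("8 " + " ".join(str(v) for v in e) + "\n")
        fh.write(f"CELL_TYPES {len(elems)}\n")
        fh.write("\n".join(["12"] * len(elems)) + "\n")
        _write_point_data(fh, len(nodes), point_data)


def write_vtk_polydata(path, points: np.ndarray, lines: np.ndarray,
                       point_data: Optional[dict] = None) -> None:
    """Polyline set (one line per network segment) with point data."""
    points = np.asarray(points, dtype=float)
    lines = np.asarray(lines, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmechangio vascular network\n"
                 "ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        fh.write(f"LINES {len(lines)} {len(lines) * 3}\n")
        for a, b in lines:
            fh.write(f"2 {a} {b}\n")
        _write_point_data(fh, len(points), point_data)


def _write_point_data(fh, n, point_data):
    if not point_data:
        return
    fh.write(f"POINT_DATA {n}\n")
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        if len(arr) != n:
            raise ValueError(
                f"point-data array {name!r} has length {len(arr)} != {n}")
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in arr:
                fh.write(_fmt(v) + "\n")
        else:
            fh.write(f"VECTORS {name} double\n")
            for v in arr:
                fh.write(" ".join(_fmt(c) for c in v) + "\n")


def write_state(mesh: Mesh, fields, network: VascularNetwork, flow,
                path_prefix, displacements=None) -> list[str]:
    """Snapshot: tissue VTK grid, network VTK polylines and the flat CSV
    segment table.  Returns the written file names."""
    prefix = str(path_prefix)
    tissue_data = {}
    if fields is not None:
        tissue_data.update({"taf": fields.taf, "oxygen": fields.oxy,
                            "mmp": fields.mmp, "ecm": fields.ecm})
    if flow is not None:
        tissue_data["p_int_mmhg"] = flow.p_int
    if displacements is not None:
        tissue_data["displacement_mm"] = displacements
    f_tissue = prefix + "_tissue.vtk"
    write_vtk_unstructured(f_tissue, mesh.nodes, mesh.elems, tissue_data)
    pos = network.current_positions(mesh, displacements)
    net_data = {"radius_um": network.radius_um,
                "state": network.state.astype(float)}
    if flow is not None:
        net_data["p_vsc_mmhg"] = flow.p_vsc
        net_data["wss_mmhg"] = flow.node_wss
    f_net = prefix + "_network.vtk"
    write_vtk_polydata(f_net, pos, network.segments, net_data)
    f_csv = prefix + "_network.csv"
    write_segment_csv(network, f_csv, positions=pos)
    return [f_tissue, f_net, f_csv]
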