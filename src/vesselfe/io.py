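"""Readers and writers: vessel networks, voxel images, field series, tables.

The native field format is a legacy-VTK ASCII unstructured-grid time series
(hexahedra plus line cells, point displacements, cell tensors, beam axial
stress as cell data) with a JSON series index, plus flat CSV tables for the
statistics.  Networks round-trip through a CSV pair (nodes / segments) or a
single JSON document with metadata; voxel images through multi-page TIFF
with a JSON sidecar carrying spacing and origin.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .meshing import BeamMesh, HexMesh
from .solver import SimulationHistory
from .synthetic import VesselNetwork, VoxelImage

__all__ = [
    "write_network_csv",
    "read_network_csv",
    "write_network_json",
    "read_network_json",
    "write_image",
    "read_image",
    "write_field_series",
    "read_field_series",
    "export_tables",
]


# ---------------------------------------------------------------------------
# vessel networks
# ---------------------------------------------------------------------------


def write_network_csv(net: VesselNetwork, nodes_path, segments_path) -> None:
    nodes = pd.DataFrame(
        {
            "id": np.arange(net.n_nodes),
            "x": net.nodes[:, 0],
            "y": net.nodes[:, 1],
            "z": net.nodes[:, 2],
            "radius": net.radii,
        }
    )
    segs = pd.DataFrame(
        {
            "id": np.arange(net.n_segments),
            "node_a": net.segments[:, 0],
            "node_b": net.segments[:, 1],
        }
    )
    nodes.to_csv(nodes_path, index=False)
    segs.to_csv(segments_path, index=False)


def read_network_csv(nodes_path, segments_path) -> VesselNetwork:
    nodes = pd.read_csv(nodes_path).sort_values("id")
    segs = pd.read_csv(segments_path).sort_values("id")
    return VesselNetwork(
        nodes=nodes[["x", "y", "z"]].to_numpy(),
        radii=nodes["radius"].to_numpy(),
        segments=segs[["node_a", "node_b"]].to_numpy(),
    )


def write_network_json(net: VesselNetwork, path) -> None:
    doc = {
        "format": "vesselfe-network-v1",
        "metadata": net.metadata,
        "nodes": [
            {"position": p.tolist(), "radius": float(r)}
            for p, r in zip(net.nodes, net.radii)
        ],
        "segments": net.segments.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def read_network_json(path) -> VesselNetwork:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "vesselfe-network-v1":
        raise ConfigError(f"{path} is not a vesselfe network file")
    return VesselNetwork(
        nodes=np.array([n["position"] for n in doc["nodes"]]),
        radii=np.array([n["radius"] for n in doc["nodes"]]),
        segments=np.array(doc["segments"], dtype=int),
        metadata=doc.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# voxel images
# ---------------------------------------------------------------------------


def write_image(img: VoxelImage, path) -> None:
    """Multi-page TIFF (pages along axis 0) + ``<path>.json`` sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(img.intensities, dtype=np.float32))
    sidecar = {
        "spacing_um": img.spacing.tolist(),
        "origin_um": img.origin.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_image(path) -> VoxelImage:
    import tifffile

    path = Path(path)
    data = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return VoxelImage(
        intensities=np.asarray(data, dtype=float),
        spacing=np.asarray(sidecar["spacing_um"]),
        origin=np.asarray(sidecar["origin_um"]),
    )


# ---------------------------------------------------------------------------
# legacy VTK unstructured grids
# ---------------------------------------------------------------------------


def _fmt(a: np.ndarray) -> str:
    return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in a)


def _write_vtk_frame(
    path: Path,
    points: np.ndarray,
    hex_cells: np.ndarray,
    line_cells: np.ndarray,
    point_data: dict,
    cell_data: dict,
    title: str,
) -> None:
    nH, nL = len(hex_cells), len(line_cells)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(points)} double",
        _fmt(points),
        f"CELLS {nH + nL} {9 * nH + 3 * nL}",
    ]
    if nH:
        lines.append(_fmt(np.hstack([np.full((nH, 1), 8), hex_cells])))
    if nL:
        lines.append(_fmt(np.hstack([np.full((nL, 1), 2), line_cells])))
    lines.append(f"CELL_TYPES {nH + nL}")
    lines.append("\n".join(["12"] * nH + ["3"] * nL))
    if point_data:
        lines.append(f"POINT_DATA {len(points)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.append(_fmt(arr))
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.append(_fmt(arr.reshape(-1, 1)))
    if cell_data:
        lines.append(f"CELL_DATA {nH + nL}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 3:
                lines.append(f"TENSORS {name} double")
                lines.append(_fmt(arr.reshape(len(arr), 9)))
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.append(_fmt(arr.reshape(-1, 1)))
    path.write_text("\n".join(lines) + "\n")


def _read_vtk_frame(path: Path):
    lines = Path(path).read_text().splitlines()
    i = 0

    def grab_floats(n_rows, width):
        nonlocal i
        vals = []
        while len(vals) < n_rows * width:
            vals.extend(float(t) for t in lines[i].split())
            i += 1
        return np.asarray(vals).reshape(n_rows, width)

    points = None
    cells_raw = None
    cell_types = None
    point_data: dict = {}
    cell_data: dict = {}
    n_points = n_cells = 0
    section = None
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0]
        if key == "POINTS":
            n_points = int(parts[1])
            i += 1
            points = grab_floats(n_points, 3)
        elif key == "CELLS":
            n_cells = int(parts[1])
            total = int(parts[2])
            i += 1
            vals = []
            while len(vals) < total:
                vals.extend(int(t) for t in lines[i].split())
                i += 1
            cells_raw = vals
        elif key == "CELL_TYPES":
            n = int(parts[1])
            i += 1
            vals = []
            while len(vals) < n:
                vals.extend(int(t) for t in lines[i].split())
                i += 1
            cell_types = np.asarray(vals)
        elif key == "POINT_DATA":
            section = point_data
            i += 1
        elif key == "CELL_DATA":
            section = cell_data
            i += 1
        elif key in ("VECTORS", "TENSORS", "SCALARS"):
            name = parts[1]
            n = n_points if section is point_data else n_cells
            width = {"VECTORS": 3, "TENSORS": 9, "SCALARS": 1}[key]
            i += 1
            if key == "SCALARS":
                i += 1  # LOOKUP_TABLE line
            data = grab_floats(n, width)
            if key == "TENSORS":
                data = data.reshape(n, 3, 3)
            elif key == "SCALARS":
                data = data.ravel()
            section[name] = data
        else:
            i += 1

    # split mixed cells by type
    hexes, lines_c = [], []
    j = 0
    for ct in cell_types:
        n = cells_raw[j]
        conn = cells_raw[j + 1: j + 1 + n]
        if ct == 12:
            hexes.append(conn)
        elif ct == 3:
            lines_c.append(conn)
        j += 1 + n
    return {
        "points": points,
        "hex_cells": np.asarray(hexes, dtype=int).reshape(-1, 8),
        "line_cells": np.asarray(lines_c, dtype=int).reshape(-1, 2),
        "point_data": point_data,
        "cell_data": cell_data,
    }


def write_field_series(
    history: SimulationHistory,
    mesh: HexMesh,
    beams: BeamMesh | None,
    path,
) -> list:
    """One legacy-VTK file per output frame plus a ``series.json`` index.

    Points are the hex nodes followed by the beam nodes; cell data carries
    the tissue Cauchy stress and Green-Lagrange strain tensors, the beam
    axial stress, and the beam reference radius as point data.  Round-trips
    losslessly through :func:`read_field_series`.
    """
    if history.n_frames == 0:
        raise ConfigError("empty history")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nN = mesh.n_nodes
    nE = mesh.n_elements
    has_beams = beams is not None and beams.n_elements > 0
    nBn = beams.n_nodes if has_beams else 0
    nB = beams.n_elements if has_beams else 0
    ref = np.vstack([mesh.nodes, beams.nodes]) if has_beams else mesh.nodes
    line_cells = beams.elements + nN if has_beams else np.zeros((0, 2), int)
    radius = np.concatenate([np.zeros(nN), beams.radii]) if has_beams \
        else np.zeros(nN)

    files = []
    for f in range(history.n_frames):
        if has_beams and history.beam_positions is not None:
            pts = np.vstack([history.positions[f], history.beam_positions[f]])
        else:
            pts = history.positions[f]
            if has_beams:
                raise ConfigError("history lacks beam positions")
        tensors_sig = np.concatenate(
            [history.hex_stress[f], np.zeros((nB, 3, 3))]
        )
        tensors_eps = np.concatenate(
            [history.hex_strain[f], np.zeros((nB, 3, 3))]
        )
        bsig = np.concatenate([np.zeros(nE), history.beam_stress[f]])
        fname = path / f"frame_{f:04d}.vtk"
        _write_vtk_frame(
            fname,
            points=pts,
            hex_cells=mesh.elements,
            line_cells=line_cells,
            point_data={
                "displacement": pts - ref,
                "beam_radius": radius,
            },
            cell_data={
                "cauchy_stress": tensors_sig,
                "green_lagrange_strain": tensors_eps,
                "beam_axial_stress": bsig,
            },
            title=f"t={history.times[f]:.17g} ms",
        )
        files.append(fname)
    index = {
        "file-series-version": "1.0",
        "files": [
            {"name": f.name, "time": float(t)}
            for f, t in zip(files, history.times)
        ],
        "element_size": mesh.element_size,
    }
    (path / "series.json").write_text(json.dumps(index, indent=1))
    return files


def read_field_series(path):
    """Rebuild (history, mesh, beams) from a written series directory."""
    path = Path(path)
    index = json.loads((path / "series.json").read_text())
    frames = [(_read_vtk_frame(path / f["name"]), f["time"])
              for f in index["files"]]
    first, _ = frames[0]
    hex_cells = first["hex_cells"]
    line_cells = first["line_cells"]
    ref = first["points"] - first["point_data"]["displacement"]
    nN = int(hex_cells.max()) + 1 if len(hex_cells) else len(ref)
    nE = len(hex_cells)
    mesh = HexMesh(nodes=ref[:nN], elements=hex_cells,
                   element_size=index.get("element_size"))
    if len(line_cells):
        beams = BeamMesh(
            nodes=ref[nN:],
            radii=first["point_data"]["beam_radius"][nN:],
            elements=line_cells - nN,
        )
    else:
        beams = None

    times, pos, bpos, sig, eps, bsig, bdir = [], [], [], [], [], [], []
    for frame, t in frames:
        times.append(t)
        pts = frame["points"]
        pos.append(pts[:nN])
        sig.append(frame["cell_data"]["cauchy_stress"][:nE])
        eps.append(frame["cell_data"]["green_lagrange_strain"][:nE])
        bsig.append(frame["cell_data"]["beam_axial_stress"][nE:])
        if beams is not None:
            bp = pts[nN:]
            bpos.append(bp)
            d = bp[beams.elements[:, 1]] - bp[beams.elements[:, 0]]
            bdir.append(d / np.linalg.norm(d, axis=1, keepdims=True))
    history = SimulationHistory(
        times=np.asarray(times),
        positions=np.asarray(pos),
        hex_stress=np.asarray(sig),
        hex_strain=np.asarray(eps),
        beam_stress=np.asarray(bsig),
        beam_direction=np.asarray(bdir) if beams is not None
        else np.zeros((len(times), 0, 3)),
        beam_positions=np.asarray(bpos) if beams is not None else None,
    )
    return history, mesh, beams


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def export_tables(records: pd.DataFrame, areas: dict, stats: dict, path) -> dict:
    """Write the records, per-ROI threshold areas, and stats summary CSVs.

    ``areas`` maps ROI name -> :func:`vesselfe.mapping.threshold_area`
    output; ROIs with no exceedance are written with explicit zeros.
    ``stats`` is a flat mapping of statistic name -> value.  Returns the
    written paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    paths = {"records": path / "records.csv",
             "areas": path / "areas.csv",
             "stats": path / "stats.csv"}
    records.to_csv(paths["records"], index=False)

    rows = []
    for roi, res in areas.items():
        for thr, area in res["area_mm2"].items():
            rows.append(
                {
                    "roi": roi,
                    "threshold_kpa": thr,
                    "area_mm2": area,
                    "fraction": res["fraction"][thr],
                }
            )
    pd.DataFrame(rows, columns=["roi", "threshold_kpa", "area_mm2", "fraction"]) \
        .to_csv(paths["areas"], index=False)

    pd.DataFrame(
        {"statistic": list(stats.keys()), "value": list(stats.values())}
    ).to_csv(paths["stats"], index=False)
    return paths
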