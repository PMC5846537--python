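"""Plain-text file formats and run manifests.

Mesh files follow a NIRFAST-style layout: a node file whose first line is
the node count followed by one "x y z region" line per node, and an element
file whose first line is the element count followed by one "i j k l" line
per tetrahedron with 1-based node indices.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .forward import MeasurementSet
from .inversion import PermissibleRegion, Reconstruction
from .mesh import DetectorGrid, Mesh

__all__ = [
    "write_mesh",
    "read_mesh",
    "write_detectors",
    "read_detectors",
    "write_measurements",
    "read_measurements",
    "write_region",
    "read_region",
    "write_reconstruction",
    "write_metrics",
    "write_manifest",
    "export_vtk",
]


def write_mesh(mesh: Mesh, node_path, element_path) -> None:
    with open(node_path, "w") as f:
        f.write(f"{mesh.n_nodes}\n")
        for (x, y, z), r in zip(mesh.nodes, mesh.region_label):
            f.write(f"{x:.12g} {y:.12g} {z:.12g} {int(r)}\n")
    with open(element_path, "w") as f:
        f.write(f"{len(mesh.elements)}\n")
        for tet in mesh.elements + 1:  # 1-based on disk
            f.write(" ".join(str(int(v)) for v in tet) + "\n")


def _parse_count(line: str, path, what: str) -> int:
    try:
        return int(line.split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: malformed header line (expected {what} count)")


def read_mesh(node_path, element_path, spacing: float = 0.0) -> Mesh:
    with open(node_path) as f:
        lines = f.read().splitlines()
    n = _parse_count(lines[0], node_path, "node")
    nodes = np.empty((n, 3))
    region = np.empty(n, dtype=np.int64)
    for i in range(n):
        parts = lines[1 + i].split()
        if len(parts) != 4:
            raise ValueError(f"{node_path}: malformed node at line {i + 2}")
        nodes[i] = [float(v) for v in parts[:3]]
        region[i] = int(parts[3])

    with open(element_path) as f:
        elines = f.read().splitlines()
    t = _parse_count(elines[0], element_path, "element")
    if t == 0:
        raise ValueError(f"{element_path}: mesh has no elements")
    elements = np.empty((t, 4), dtype=np.int64)
    for i in range(t):
        parts = elines[1 + i].split()
        if len(parts) != 4:
            raise ValueError(f"{element_path}: malformed element at line {i + 2}")
        tet = np.array([int(v) for v in parts]) - 1
        if tet.min() < 0 or tet.max() >= n:
            raise ValueError(
                f"{element_path}: element at line {i + 2} references node "
                f"{tet.max() + 1} outside 1..{n}"
            )
        elements[i] = tet

    if spacing <= 0:  # infer the nominal spacing from the shortest edge
        p = nodes[elements[0]]
        spacing = float(
            min(np.linalg.norm(p[a] - p[b]) for a in range(4) for b in range(a + 1, 4))
        )
    return Mesh(nodes=nodes, elements=elements, region_label=region, spacing=spacing)


def write_detectors(grid: DetectorGrid, path) -> None:
    pd.DataFrame(grid.positions, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_detectors(path, face: str = "z+", pitch: float = 0.0) -> DetectorGrid:
    df = pd.read_csv(path)
    positions = df[["x", "y", "z"]].to_numpy(dtype=float)
    return DetectorGrid(positions=positions, face=face, pitch=pitch, extent=(0.0, 0.0))


def write_measurements(mset: MeasurementSet, csv_path, n_detectors: int) -> None:
    """CSV (detector_id, wavelength_nm, value) plus a JSON provenance sidecar."""
    rows = []
    for row, value in enumerate(mset.values):
        det = row % n_detectors
        lam = mset.wavelengths[row // n_detectors]
        rows.append({"detector_id": det, "wavelength_nm": lam, "value": value})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    sidecar = Path(str(csv_path) + ".json")
    sidecar.write_text(json.dumps({
        "wavelengths_nm": list(mset.wavelengths),
        "n_detectors": n_detectors,
        "provenance": mset.provenance,
    }, indent=2))


def read_measurements(csv_path) -> MeasurementSet:
    df = pd.read_csv(csv_path)
    sidecar = Path(str(csv_path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    wavelengths = tuple(meta.get(
        "wavelengths_nm", sorted(df["wavelength_nm"].unique())
    ))
    df = df.sort_values(["wavelength_nm", "detector_id"], kind="stable")
    order = {w: i for i, w in enumerate(wavelengths)}
    df = df.iloc[np.argsort([
        order[w] * (df["detector_id"].max() + 1) + d
        for w, d in zip(df["wavelength_nm"], df["detector_id"])
    ], kind="stable")]
    return MeasurementSet(
        values=df["value"].to_numpy(dtype=float),
        wavelengths=wavelengths,
        provenance=meta.get("provenance", {"noise": "unknown"}),
    )


def write_region(region: PermissibleRegion, path) -> None:
    Path(path).write_text(json.dumps({
        "method_tag": region.method_tag,
        "us_position": list(region.us_position) if region.us_position else None,
        "d": region.d,
        "reference_node": region.reference_node,
        "noi": [int(v) for v in region.noi],
    }, indent=2))


def read_region(path) -> PermissibleRegion:
    data = json.loads(Path(path).read_text())
    return PermissibleRegion(
        noi=np.asarray(data["noi"], dtype=np.int64),
        method_tag=data["method_tag"],
        reference_node=data.get("reference_node"),
        us_position=tuple(data["us_position"]) if data.get("us_position") else None,
        d=data.get("d"),
    )


def write_reconstruction(recon: Reconstruction, csv_path, stats_path=None) -> None:
    pd.DataFrame({
        "node_id": np.arange(len(recon.x_hat)),
        "x_hat": recon.x_hat,
    }).to_csv(csv_path, index=False)
    if stats_path is not None:
        Path(stats_path).write_text(json.dumps(recon.solver_stats, indent=2))


def read_reconstruction(csv_path) -> np.ndarray:
    return pd.read_csv(csv_path)["x_hat"].to_numpy(dtype=float)


def write_metrics(trials: pd.DataFrame, summary: pd.DataFrame, csv_path, json_path) -> None:
    trials.to_csv(csv_path, index=False)
    Path(json_path).write_text(summary.to_json(orient="records", indent=2))


def write_manifest(path, config: dict, inputs: dict | None = None, seeds=None) -> dict:
    """Record tool version, a hash of the configuration, input digests and
    seeds so that every output is reproducible from its manifest."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "tool": "usblt",
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "input_digests": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in (inputs or {}).items()
        },
        "seeds": list(seeds) if seeds is not None else [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def export_vtk(mesh: Mesh, path, point_data: dict | None = None) -> None:
    """Minimal legacy-ASCII VTK unstructured-grid export for visualization."""
    lines = [
        "# vtk DataFile Version 3.0", "usblt mesh", "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.nodes]
    t = len(mesh.elements)
    lines.append(f"CELLS {t} {5 * t}")
    lines += ["4 " + " ".join(str(int(v)) for v in tet) for tet in mesh.elements]
    lines.append(f"CELL_TYPES {t}")
    lines += ["10"] * t  # VTK_TETRA
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in np.asarray(values, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")
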