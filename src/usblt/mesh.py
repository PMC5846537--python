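"""Structured slab meshes and detector grids for diffuse-optics simulations.

A slab of dimensions (Lx, Ly, Lz) mm is discretised on a regular grid of
nodes (spacing ``h``) and each grid cube is split into six tetrahedra along
its main diagonal (the Kuhn split, applied with the same orientation in
every cube, which makes the decomposition conforming).  Interior nodes all
receive the same lumped volume h^3 under this split, so the total
sensitivity varies smoothly in space — a property the dynamic-range region
selection relies on.

Coordinate convention: x in [-Lx/2, Lx/2], y in [-Ly/2, Ly/2], z in [0, Lz].
Detectors conventionally sit on the z = Lz face, so the *depth* of a source
is Lz - z_source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mesh",
    "DetectorGrid",
    "build_slab_mesh",
    "place_detector_grid",
    "nearest_node",
    "node_volumes",
    "element_volumes",
]

# Kuhn split: six tetrahedra per cube, one per permutation of the axes,
# each walking from corner (0,0,0) to (1,1,1) one axis at a time.  Every
# tetrahedron contains the main diagonal, so all cubes share compatible
# face diagonals and the decomposition is conforming.
def _cube_patterns() -> list[tuple[tuple[int, int, int], ...]]:
    from itertools import permutations

    tets = []
    for perm in sorted(permutations(range(3))):
        corner = [0, 0, 0]
        path = [tuple(corner)]
        for axis in perm:
            corner[axis] = 1
            path.append(tuple(corner))
        tets.append(tuple(path))
    return tets


@dataclass
class Mesh:
    """Tetrahedral mesh: node coordinates (mm), elements, per-node region id."""

    nodes: np.ndarray          # (N, 3) float64
    elements: np.ndarray       # (T, 4) int64
    region_label: np.ndarray   # (N,) int
    spacing: float             # nominal inter-node distance (mm)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.region_label = np.asarray(self.region_label, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be an (N, 3) array")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise ValueError("element refers to a node index out of range")
        if self.region_label.shape != (len(self.nodes),):
            raise ValueError("region_label must have one entry per node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.nodes.min(axis=0), self.nodes.max(axis=0)


@dataclass
class DetectorGrid:
    """Regular grid of detector positions on one boundary face of a slab."""

    positions: np.ndarray      # (P, 3) mm
    face: str                  # 'x-', 'x+', 'y-', 'y+', 'z-', 'z+'
    pitch: float               # mm
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)

    @property
    def n_detectors(self) -> int:
        return len(self.positions)


def _axis_count(length: float, spacing: float, axis: str) -> int:
    ratio = length / spacing
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"dimension along {axis} ({length} mm) is not an integral multiple "
            f"of the spacing ({spacing} mm)"
        )
    return int(round(ratio)) + 1


def build_slab_mesh(dimensions: tuple[float, float, float], spacing: float) -> Mesh:
    """Build a regular tetrahedral slab mesh.

    Parameters
    ----------
    dimensions : (Lx, Ly, Lz) in mm, each an integral multiple of ``spacing``.
    spacing : nominal node distance in mm.

    Returns
    -------
    Mesh with (Lx/h+1)(Ly/h+1)(Lz/h+1) nodes and 6 tetrahedra per grid cube,
    all nodes labelled region 1 (homogeneous).
    """
    lx, ly, lz = (float(v) for v in dimensions)
    if min(lx, ly, lz) <= 0 or spacing <= 0:
        raise ValueError("dimensions and spacing must be positive")
    nx = _axis_count(lx, spacing, "x")
    ny = _axis_count(ly, spacing, "y")
    nz = _axis_count(lz, spacing, "z")

    xs = -lx / 2 + spacing * np.arange(nx)
    ys = -ly / 2 + spacing * np.arange(ny)
    zs = spacing * np.arange(nz)
    # node index = i + nx*(j + ny*k): x fastest, z slowest
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    ci, cj, ck = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()

    def corner(d):  # global node index of cube corner (dx,dy,dz)
        return (ci + d[0]) + nx * ((cj + d[1]) + ny * (ck + d[2]))

    patterns = _cube_patterns()
    ncubes = len(ci)
    elements = np.empty((ncubes, 6, 4), dtype=np.int64)
    for t, pattern in enumerate(patterns):
        for v, local in enumerate(pattern):
            elements[:, t, v] = corner(local)
    elements = elements.reshape(-1, 4)

    return Mesh(
        nodes=nodes,
        elements=elements,
        region_label=np.ones(len(nodes), dtype=np.int64),
        spacing=float(spacing),
    )


_FACES = {"x-": (0, "min"), "x+": (0, "max"), "y-": (1, "min"), "y+": (1, "max"),
          "z-": (2, "min"), "z+": (2, "max")}


def place_detector_grid(
    mesh: Mesh,
    extent: tuple[float, float],
    pitch: float,
    face: str = "z+",
    center: tuple[float, float] = (0.0, 0.0),
) -> DetectorGrid:
    """Place a regular (w/pitch+1) x (h/pitch+1) detector grid on one face.

    ``extent`` = (width, height) in the face's in-plane axes; a zero extent
    along both axes yields a single detector at ``center``.
    """
    if face not in _FACES:
        raise ValueError(f"unknown face {face!r}; expected one of {sorted(_FACES)}")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    w, h = (float(v) for v in extent)
    if w < 0 or h < 0:
        raise ValueError("extent must be nonnegative")

    def _count(length: float, label: str) -> int:
        if length == 0:
            return 1
        ratio = length / pitch
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"extent {label} ({length} mm) is not an integral multiple of pitch")
        return int(round(ratio)) + 1

    nu, nv = _count(w, "width"), _count(h, "height")
    axis, side = _FACES[face]
    lo, hi = mesh.bounds
    plane_value = lo[axis] if side == "min" else hi[axis]
    in_plane = [a for a in range(3) if a != axis]

    us = center[0] - w / 2 + pitch * np.arange(nu) if nu > 1 else np.array([center[0]])
    vs = center[1] - h / 2 + pitch * np.arange(nv) if nv > 1 else np.array([center[1]])
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    positions = np.empty((nu * nv, 3))
    positions[:, axis] = plane_value
    positions[:, in_plane[0]] = uu.ravel()
    positions[:, in_plane[1]] = vv.ravel()

    for a in in_plane:
        if positions[:, a].min() < lo[a] - 1e-9 or positions[:, a].max() > hi[a] + 1e-9:
            raise ValueError("detector grid exceeds the face bounds")
    return DetectorGrid(positions=positions, face=face, pitch=float(pitch), extent=(w, h))


def nearest_node(mesh: Mesh, point) -> int:
    """Index of the node nearest to ``point`` (ties broken to the lowest index)."""
    point = np.asarray(point, dtype=float)
    if point.shape != (3,) or not np.all(np.isfinite(point)):
        raise ValueError("point must be a finite 3-vector")
    if mesh.n_nodes == 0:
        raise ValueError("mesh has no nodes")
    d2 = np.einsum("ij,ij->i", mesh.nodes - point, mesh.nodes - point)
    return int(np.argmin(d2))  # argmin returns the first (lowest) index on ties


def element_volumes(mesh: Mesh) -> np.ndarray:
    """Volume (mm^3) of every tetrahedron; raises on degenerate elements."""
    p = mesh.nodes[mesh.elements]            # (T, 4, 3)
    edges = p[:, 1:, :] - p[:, :1, :]        # (T, 3, 3)
    vol = np.abs(np.linalg.det(edges)) / 6.0
    if mesh.elements.size and vol.min() <= 0:
        raise ValueError("mesh contains a degenerate (zero-volume) tetrahedron")
    return vol


def node_volumes(mesh: Mesh) -> np.ndarray:
    """Lumped nodal volumes: each tetrahedron gives a quarter of its volume
    to each vertex (row sums of the lumped FEM mass matrix).  Sums to the
    total mesh volume."""
    vol = element_volumes(mesh)
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.elements.ravel(), np.repeat(vol / 4.0, 4))
    return out
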