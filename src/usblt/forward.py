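"""Multi-wavelength BLT forward model: Jacobian assembly and measurements.

The linear model is y = J x, where x holds nodal bioluminescent source
intensities and y stacks all (detector, wavelength) boundary readings.
By reciprocity of the symmetric diffusion operator, the row of J for
detector j at wavelength lambda is

    J[(lambda, j), n] = gamma_lambda * Phi_adj[n] * V_n,

with Phi_adj the adjoint Green's field of a unit source at the boundary
node nearest detector j, V_n the lumped nodal volume, and gamma_lambda the
source emission weight at that wavelength (weights sum to 1).  One FEM
solve per (detector, wavelength) is required; the factorization is shared
across detectors at each wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import DiffusionSolver, assemble_system
from .mesh import DetectorGrid, Mesh, nearest_node, node_volumes
from .spectral import SpectralModel, absorption_at, diffusion_coefficient, scattering_at

__all__ = [
    "Jacobian",
    "MeasurementSet",
    "optical_properties",
    "build_jacobian",
    "forward_measurements",
]


@dataclass
class Jacobian:
    """Stacked multi-wavelength sensitivity matrix (M_total x N).

    Row order is wavelength-major: all detectors at the first wavelength,
    then all detectors at the second, and so on.
    """

    matrix: np.ndarray                 # (M_total, N), nonnegative
    wavelengths: tuple[float, ...]     # nm
    emission_weights: np.ndarray       # per-wavelength gamma, sums to 1
    n_detectors: int

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[1]

    @property
    def m_total(self) -> int:
        return self.matrix.shape[0]

    def row_of(self, detector: int, wavelength_index: int) -> int:
        if not (0 <= detector < self.n_detectors):
            raise ValueError("detector index out of range")
        if not (0 <= wavelength_index < len(self.wavelengths)):
            raise ValueError("wavelength index out of range")
        return wavelength_index * self.n_detectors + detector

    def detector_of_row(self, row: int) -> tuple[int, int]:
        """Inverse row map: row -> (detector, wavelength_index)."""
        if not (0 <= row < self.m_total):
            raise ValueError("row index out of range")
        return row % self.n_detectors, row // self.n_detectors


@dataclass
class MeasurementSet:
    """Boundary readings with noise provenance."""

    values: np.ndarray
    wavelengths: tuple[float, ...]
    provenance: dict = field(default_factory=lambda: {"noise": "none"})

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def optical_properties(
    mesh: Mesh,
    model: SpectralModel | dict[int, SpectralModel],
    wavelength_nm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node (mu_a, kappa) at one wavelength.

    ``model`` is either a single SpectralModel (homogeneous) or a mapping
    region label -> SpectralModel for heterogeneous meshes.
    """
    n = mesh.n_nodes
    if isinstance(model, dict):
        mua = np.empty(n)
        kappa = np.empty(n)
        for region in np.unique(mesh.region_label):
            if region not in model:
                raise ValueError(f"no spectral model for region {region}")
            m = model[region]
            mask = mesh.region_label == region
            a = absorption_at(m, wavelength_nm)
            s = scattering_at(m, wavelength_nm)
            mua[mask] = a
            kappa[mask] = diffusion_coefficient(a, s)
        return mua, kappa
    a = absorption_at(model, wavelength_nm)
    s = scattering_at(model, wavelength_nm)
    return np.full(n, a), np.full(n, diffusion_coefficient(a, s))


def _refractive_index(model) -> float:
    if isinstance(model, dict):
        # boundary mismatch from the first region's index (exterior interface)
        return next(iter(model.values())).refractive_index
    return model.refractive_index


def _check_on_boundary(mesh: Mesh, positions: np.ndarray) -> None:
    lo, hi = mesh.bounds
    on_face = np.zeros(len(positions), dtype=bool)
    for axis in range(3):
        on_face |= np.abs(positions[:, axis] - lo[axis]) < 1e-6
        on_face |= np.abs(positions[:, axis] - hi[axis]) < 1e-6
    inside = np.all((positions >= lo - 1e-6) & (positions <= hi + 1e-6), axis=1)
    if not np.all(on_face & inside):
        bad = int(np.argmin(on_face & inside))
        raise ValueError(f"detector {bad} at {positions[bad]} is not on the mesh boundary")


def build_jacobian(
    mesh: Mesh,
    detectors: DetectorGrid,
    model: SpectralModel | dict[int, SpectralModel],
    wavelengths,
    emission_weights=None,
) -> Jacobian:
    """Assemble the stacked multi-wavelength Jacobian by adjoint solves."""
    wavelengths = tuple(float(w) for w in wavelengths)
    nlam = len(wavelengths)
    if nlam == 0:
        raise ValueError("at least one wavelength is required")
    if emission_weights is None:
        gamma = np.full(nlam, 1.0 / nlam)
    else:
        gamma = np.asarray(emission_weights, dtype=float)
        if gamma.shape != (nlam,):
            raise ValueError("one emission weight per wavelength is required")
        if abs(gamma.sum() - 1.0) > 1e-8:
            raise ValueError("emission weights must sum to 1")

    _check_on_boundary(mesh, detectors.positions)
    adj_nodes = [nearest_node(mesh, p) for p in detectors.positions]
    volumes = node_volumes(mesh)
    n_det = detectors.n_detectors

    matrix = np.empty((nlam * n_det, mesh.n_nodes))
    for li, lam in enumerate(wavelengths):
        mua, kappa = optical_properties(mesh, model, lam)
        system = assemble_system(mesh, mua, kappa, _refractive_index(model))
        solver = DiffusionSolver(system)
        field_cache: dict[int, np.ndarray] = {}
        for di, node in enumerate(adj_nodes):
            if node not in field_cache:
                field_cache[node] = solver.solve_green(node)
            matrix[li * n_det + di] = gamma[li] * field_cache[node] * volumes
    return Jacobian(
        matrix=matrix,
        wavelengths=wavelengths,
        emission_weights=gamma,
        n_detectors=n_det,
    )


def forward_measurements(jacobian: Jacobian, x: np.ndarray) -> MeasurementSet:
    """Noiseless boundary data y = J x for a nodal source vector x >= 0."""
    x = np.asarray(x, dtype=float)
    if x.shape != (jacobian.n_nodes,):
        raise ValueError(
            f"source vector length {x.shape} does not match the Jacobian "
            f"({jacobian.n_nodes} nodes)"
        )
    if x.min() < 0:
        raise ValueError("source intensities must be nonnegative")
    return MeasurementSet(
        values=jacobian.matrix @ x,
        wavelengths=jacobian.wavelengths,
        provenance={"noise": "none"},
    )
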