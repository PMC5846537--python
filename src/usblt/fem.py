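"""Continuous-wave diffusion FEM on tetrahedral meshes.

Solves (-div kappa grad + mu_a) Phi = q with the Robin (type-III) boundary
condition  kappa dPhi/dn + Phi / (2 A(n)) = 0,  where A(n) accounts for the
refractive-index mismatch at the tissue-air interface via the
Groenhuis/Keijzer polynomial approximation.  Linear (P1) elements; the
absorption term uses the consistent element mass matrix, whose row sums per
element equal V/4 (so the lumped row sums are the nodal volumes).
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh

__all__ = [
    "boundary_mismatch_factor",
    "boundary_faces",
    "assemble_system",
    "DiffusionSolver",
]

_DIRECT_LIMIT = 100_000  # above this many nodes fall back to iterative CG


def boundary_mismatch_factor(n: float) -> float:
    """Internal-reflection parameter A(n) (Groenhuis/Keijzer form).

    A(1) = 1 (matched boundary); A(1.33) ~ 2.95 for a tissue-air interface.
    """
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if n == 1.0:
        return 1.0
    r0 = ((n - 1.0) / (n + 1.0)) ** 2
    theta_c = np.arcsin(1.0 / n)
    cos_c = abs(np.cos(theta_c))
    return (2.0 / (1.0 - r0) - 1.0 + cos_c**3) / (1.0 - cos_c**2)


def boundary_faces(elements: np.ndarray) -> np.ndarray:
    """Triangular faces that belong to exactly one tetrahedron."""
    local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    faces = np.concatenate([elements[:, idx] for idx in local], axis=0)
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[first[counts == 1]]


def _element_geometry(nodes: np.ndarray, elements: np.ndarray):
    p = nodes[elements]                       # (T, 4, 3)
    edge = np.swapaxes(p[:, 1:, :] - p[:, :1, :], 1, 2)   # columns = edge vectors
    det = np.linalg.det(edge)
    vol = np.abs(det) / 6.0
    if vol.min() <= 0:
        raise ValueError("degenerate tetrahedron in mesh; cannot assemble FEM system")
    inv = np.linalg.inv(edge)                 # rows m of inv are grad xi_m
    grads = np.empty((len(elements), 4, 3))
    grads[:, 1:, :] = inv
    grads[:, 0, :] = -inv.sum(axis=1)
    return vol, grads


def assemble_system(
    mesh: Mesh,
    mua: np.ndarray,
    kappa: np.ndarray,
    refractive_index: float = 1.33,
    robin: bool = True,
) -> sp.csc_matrix:
    """Assemble the symmetric FEM system K = stiffness(kappa) + mass(mu_a)
    [+ Robin boundary term].  Per-node properties are averaged per element."""
    mua = np.asarray(mua, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if mua.shape != (mesh.n_nodes,) or kappa.shape != (mesh.n_nodes,):
        raise ValueError("property vectors must have one entry per node")

    elems = mesh.elements
    vol, grads = _element_geometry(mesh.nodes, elems)
    kappa_e = kappa[elems].mean(axis=1)
    mua_e = mua[elems].mean(axis=1)

    # element stiffness: V * kappa * (g_i . g_j)
    ke = (kappa_e * vol)[:, None, None] * np.einsum("tid,tjd->tij", grads, grads)
    # consistent element mass: mu_a * V/20 * (1 + delta_ij)
    mass_pattern = (np.ones((4, 4)) + np.eye(4)) / 20.0
    ke += (mua_e * vol)[:, None, None] * mass_pattern

    rows = np.repeat(elems, 4, axis=1).ravel()
    cols = np.tile(elems, (1, 4)).ravel()
    data = ke.ravel()

    if robin:
        faces = boundary_faces(elems)
        pf = mesh.nodes[faces]
        area = 0.5 * np.linalg.norm(
            np.cross(pf[:, 1] - pf[:, 0], pf[:, 2] - pf[:, 0]), axis=1
        )
        a_factor = boundary_mismatch_factor(refractive_index)
        face_pattern = (np.ones((3, 3)) + np.eye(3)) / 12.0
        fe = (area / (2.0 * a_factor))[:, None, None] * face_pattern
        rows = np.concatenate([rows, np.repeat(faces, 3, axis=1).ravel()])
        cols = np.concatenate([cols, np.tile(faces, (1, 3)).ravel()])
        data = np.concatenate([data, fe.ravel()])

    n = mesh.n_nodes
    k = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsc()
    k.sum_duplicates()
    return k


class DiffusionSolver:
    """Factorized solver for one assembled diffusion system.

    Uses a direct sparse LU factorization (reused across right-hand sides)
    for meshes below 1e5 nodes, and diagonally preconditioned CG above.
    """

    def __init__(self, system: sp.spmatrix, tol: float = 1e-10):
        self.system = system.tocsc()
        self.tol = tol
        self.n = system.shape[0]
        self._direct = self.n < _DIRECT_LIMIT
        if self._direct:
            self._lu = spla.splu(self.system)
        else:
            diag = self.system.diagonal()
            self._precond = spla.LinearOperator(
                self.system.shape, matvec=lambda v: v / diag
            )

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        rhs = np.asarray(rhs, dtype=float)
        if rhs.shape != (self.n,):
            raise ValueError("right-hand side has the wrong length")
        if not rhs.any():
            return np.zeros(self.n)
        if self._direct:
            phi = self._lu.solve(rhs)
        else:
            phi, info = spla.cg(self.system, rhs, rtol=self.tol, maxiter=5000,
                                M=self._precond)
            if info != 0:
                res = np.linalg.norm(self.system @ phi - rhs)
                raise RuntimeError(f"diffusion CG did not converge; residual {res:.3e}")
        res = np.linalg.norm(self.system @ phi - rhs)
        if res > 1e-6 * max(np.linalg.norm(rhs), 1e-300):
            raise RuntimeError(f"diffusion solve inaccurate; residual {res:.3e}")
        return phi

    def solve_green(self, source_node: int) -> np.ndarray:
        """Field of a unit point source at ``source_node`` (K Phi = e_q).

        Small negative overshoots from the discretization are clipped to 0;
        a warning is raised if any clip exceeds 1e-10 of the field maximum.
        """
        if not (0 <= source_node < self.n):
            raise ValueError("source node index out of range")
        rhs = np.zeros(self.n)
        rhs[source_node] = 1.0
        phi = self.solve(rhs)
        neg = phi < 0
        if neg.any():
            worst = -phi[neg].min()
            if worst > 1e-10 * phi.max():
                warnings.warn(
                    f"clipped negative field values up to {worst:.3e} "
                    f"({worst / phi.max():.2e} of the field maximum)",
                    RuntimeWarning,
                )
            phi = np.where(neg, 0.0, phi)
        return phi
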