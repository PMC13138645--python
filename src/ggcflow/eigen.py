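"""Geometric eigenmodes of a closed surface.

The Laplace-Beltrami operator is discretized with linear (P1) finite
elements: the classical cotangent stiffness matrix A and the consistent mass
matrix B.  Eigenmodes solve the generalized problem A x = lambda B x
(equivalently the Helmholtz equation on the surface); on a closed connected
mesh the first eigenvalue is zero with a constant eigenfunction, and the
low-order modes encode the surface's long-wavelength shape.

Eigenvalues carry units mm^-2 and scale as 1/R^2 under uniform scaling by R;
the unit sphere's spectrum is l(l+1) with multiplicity 2l+1, which the tests
use as an analytic oracle.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ArgumentError, DataValidationError, NumericalError
from .mesh import TriangleMesh, triangle_areas

__all__ = ["EigenmodeSet", "build_fem_matrices", "solve_eigenmodes", "fix_sign"]


@dataclass(frozen=True)
class EigenmodeSet:
    """Mass-orthonormal eigenpairs of the surface Laplacian.

    ``eigenvalues`` are nondecreasing and nonnegative (mm^-2); ``modes`` is
    (N, K) with one column per mode ("Mode 1..K", Mode 1 the constant).
    ``mass_matrix_signature`` is a checksum of the discretization so exported
    modes can be traced back to the mesh they were computed on.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    mass_matrix_signature: str = ""

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        phi = np.asarray(self.modes, dtype=np.float64)
        if phi.ndim != 2 or phi.shape[1] != lam.size:
            raise DataValidationError("modes must be (N, K) matching eigenvalues")
        if lam.size < 2:
            raise DataValidationError("an EigenmodeSet needs at least 2 modes")
        object.__setattr__(self, "eigenvalues", lam)
        object.__setattr__(self, "modes", phi)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_vertices(self) -> int:
        return self.modes.shape[0]

    def mode(self, index: int) -> np.ndarray:
        """Return mode by 1-based index (Mode 1 is the constant)."""
        if not 1 <= index <= self.n_modes:
            raise ArgumentError(f"mode index {index} outside 1..{self.n_modes}")
        return self.modes[:, index - 1]


def build_fem_matrices(mesh: TriangleMesh) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Assemble the P1 cotangent stiffness and consistent mass matrices.

    Returns
    -------
    stiffness : (N, N) sparse symmetric
        Cotangent Laplacian with zero row sums (constants in the null space).
    mass : (N, N) sparse symmetric
        Consistent P1 mass matrix; its total entry sum equals the surface
        area.
    """
    v = mesh.vertices
    f = mesh.faces
    n = mesh.n_vertices
    areas = triangle_areas(mesh)

    # cotangent of the angle at each corner: cot = (e1 . e2) / |e1 x e2|
    rows, cols, a_vals = [], [], []
    m_rows, m_cols, m_vals = [], [], []
    for corner in range(3):
        i = f[:, corner]
        j = f[:, (corner + 1) % 3]
        k = f[:, (corner + 2) % 3]
        e1 = v[j] - v[i]
        e2 = v[k] - v[i]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / cross
        if not np.isfinite(cot).all():
            bad = int(np.flatnonzero(~np.isfinite(cot))[0])
            raise DataValidationError(
                f"non-finite cotangent weight in face {bad}: degenerate triangle"
            )
        w = 0.5 * cot
        # angle at corner i weights the opposite edge (j, k)
        rows += [j, k, j, k]
        cols += [k, j, j, k]
        a_vals += [-w, -w, w, w]

    stiffness = sp.csr_matrix(
        (np.concatenate(a_vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    # consistent mass: A/6 on the diagonal per corner, A/12 per ordered pair
    for ci in range(3):
        for cj in range(3):
            m_rows.append(f[:, ci])
            m_cols.append(f[:, cj])
            m_vals.append(areas / (6.0 if ci == cj else 12.0))
    mass = sp.csr_matrix(
        (np.concatenate(m_vals), (np.concatenate(m_rows), np.concatenate(m_cols))),
        shape=(n, n),
    )
    return stiffness, mass


def fix_sign(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the maximum-|value| entry is positive.

    Ties in |value| are resolved by the lowest index (argmax behaviour).
    """
    modes = np.array(modes, dtype=np.float64, copy=True)
    idx = np.abs(modes).argmax(axis=0)
    flip = modes[idx, np.arange(modes.shape[1])] < 0
    modes[:, flip] *= -1.0
    return modes


def _mass_signature(mass: sp.spmatrix) -> str:
    coo = mass.tocoo()
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(coo.row).tobytes())
    h.update(np.ascontiguousarray(coo.col).tobytes())
    h.update(np.ascontiguousarray(np.round(coo.data, 12)).tobytes())
    return h.hexdigest()[:16]


def solve_eigenmodes(
    mesh: TriangleMesh,
    n_modes: int = 100,
    tol: float = 1e-10,
) -> EigenmodeSet:
    """Smallest ``n_modes`` eigenpairs of the surface Laplacian.

    Uses shift-invert (shift -1e-8) so the zero mode of a closed mesh is
    extracted robustly.  Modes are mass-orthonormal, eigenvalues ascending,
    and the sign convention of :func:`fix_sign` is applied columnwise.
    """
    if n_modes < 2:
        raise ArgumentError("n_modes must be >= 2")
    if n_modes >= mesh.n_vertices:
        raise ArgumentError(
            f"n_modes={n_modes} must be < vertex count {mesh.n_vertices}"
        )
    stiffness, mass = build_fem_matrices(mesh)
    n = mesh.n_vertices
    # deterministic start vector (eigsh would otherwise draw a random one);
    # generous subspace so degenerate clusters keep their full multiplicity
    v0 = np.sin(np.arange(1, n + 1, dtype=np.float64))
    ncv = min(n, max(2 * n_modes + 1, n_modes + 40))
    try:
        eigenvalues, modes = spla.eigsh(
            stiffness, k=n_modes, M=mass, sigma=-1e-8, which="LM", tol=tol,
            v0=v0, ncv=ncv,
        )
    except Exception as exc:
        raise NumericalError(
            f"eigenmode solver failed on mesh with {mesh.n_vertices} vertices "
            f"(k={n_modes}): {exc}"
        ) from exc
    order = np.argsort(eigenvalues)
    eigenvalues = eigenvalues[order]
    modes = fix_sign(modes[:, order])
    eigenvalues = np.clip(eigenvalues, 0.0, None)  # clip -O(1e-12) round-off

    if eigenvalues[1] < 1e-8 * max(eigenvalues[-1], 1.0):
        raise NumericalError(
            "more than one (near-)zero eigenvalue: the mesh appears disconnected"
        )
    return EigenmodeSet(eigenvalues, modes, _mass_signature(mass))
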