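"""Triangle-mesh data model and surface morphometry.

A :class:`TriangleMesh` is the substrate for every geometric quantity in the
pipeline: triangle and vertex areas, the outer (convex) contour, the
gyrification index (GI), and per-region surface areas.  Coordinates are
treated as millimeters throughout; no unit inference is performed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from .errors import ArgumentError, DataValidationError

__all__ = [
    "TriangleMesh",
    "VertexScalarMap",
    "MorphometryResult",
    "surface_area",
    "triangle_areas",
    "vertex_areas",
    "outer_contour",
    "gyrification_index",
    "regional_surface_area",
]

_MIN_FACE_AREA = 1e-12  # mm^2; faces below this are degenerate


@dataclass(frozen=True)
class TriangleMesh:
    """Triangulated surface in millimeter coordinates.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates (right-anterior-superior convention assumed).
    faces : (M, 3) int array
        0-based vertex indices per triangle.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise DataValidationError(f"vertices must be (N, 3); got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise DataValidationError(f"faces must be (M, 3); got {f.shape}")
        if not np.isfinite(v).all():
            raise DataValidationError("vertices contain non-finite coordinates")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise DataValidationError(
                f"face indices must lie in [0, {len(v)}); "
                f"found range [{f.min()}, {f.max()}]"
            )
        repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if repeated.any():
            raise DataValidationError(
                f"faces with repeated vertex indices: {np.flatnonzero(repeated)[:5].tolist()}"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        areas = triangle_areas(self, validate=False)
        bad = np.flatnonzero(areas < _MIN_FACE_AREA)
        if bad.size:
            raise DataValidationError(
                f"degenerate faces (area < {_MIN_FACE_AREA} mm^2) at indices "
                f"{bad[:5].tolist()}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def validate_closed(self) -> None:
        if not self.is_closed():
            raise DataValidationError(
                "mesh is not closed: some edge is not shared by exactly 2 faces"
            )


@dataclass(frozen=True)
class VertexScalarMap:
    """One finite real value per mesh vertex (e.g., 'SG1' or 'Mode3')."""

    values: np.ndarray
    name: str = "map"
    units: str = "GV"

    def __post_init__(self) -> None:
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64)).ravel()
        if not np.isfinite(vals).all():
            raise DataValidationError(f"map '{self.name}' contains non-finite values")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MorphometryResult:
    total_area: float
    hull_area: float
    gi: float
    regional_areas: dict = field(default_factory=dict)


def triangle_areas(mesh: TriangleMesh, validate: bool = True) -> np.ndarray:
    """Per-face areas via the cross-product formula, in mm^2."""
    v = mesh.vertices
    f = mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    if validate:
        bad = np.flatnonzero(areas < _MIN_FACE_AREA)
        if bad.size:
            raise DataValidationError(f"degenerate face at index {bad[0]}")
    return areas


def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area (mm^2): sum of triangle areas."""
    return float(triangle_areas(mesh).sum())


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident triangle.

    The sum over vertices equals :func:`surface_area` up to accumulation
    round-off.
    """
    areas = triangle_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    third = areas / 3.0
    for col in range(3):
        np.add.at(out, mesh.faces[:, col], third)
    return out


def outer_contour(mesh: TriangleMesh) -> TriangleMesh:
    """Convex hull of the vertex set as a closed triangulated mesh."""
    if mesh.n_vertices < 4:
        raise DataValidationError("need at least 4 vertices for an outer contour")
    try:
        hull = _trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces, process=False
        ).convex_hull
    except Exception as exc:  # qhull raises on coplanar/degenerate input
        raise DataValidationError(f"degenerate geometry, no 3D hull: {exc}") from exc
    return TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces))


def gyrification_index(mesh: TriangleMesh) -> float:
    """Folding complexity: pial area divided by outer-contour (hull) area.

    Convex shapes give 1; the more folded the surface, the larger the index.
    Scale-invariant because both areas scale with the square of any common
    scale factor.
    """
    hull = outer_contour(mesh)
    return surface_area(mesh) / surface_area(hull)


def morphometry(mesh: TriangleMesh, labels: np.ndarray | None = None) -> MorphometryResult:
    """Bundle total area, hull area, GI, and (optionally) regional areas."""
    total = surface_area(mesh)
    hull = surface_area(outer_contour(mesh))
    regional = regional_surface_area(mesh, labels) if labels is not None else {}
    return MorphometryResult(total, hull, total / hull, regional)


def regional_surface_area(mesh: TriangleMesh, labels) -> dict:
    """Sum of barycentric vertex areas per label.

    Labels absent from the input never appear in the output, and the regional
    totals partition the full surface area.
    """
    labels = np.asarray(labels).ravel()
    if len(labels) != mesh.n_vertices:
        raise ArgumentError(
            f"labels length {len(labels)} != vertex count {mesh.n_vertices}"
        )
    va = vertex_areas(mesh)
    return {
        lab.item(): float(va[labels == lab].sum())
        for lab in np.unique(labels)
    }
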