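"""Spin-test spatial permutation inference.

Smooth brain maps violate the independence assumption of parametric
correlation tests, inflating false positives.  The spin test builds a null
distribution that preserves spatial autocorrelation: vertices are projected
onto a sphere, the sphere is rotated by Haar-uniform random rotations, and
the map is remapped to the nearest rotated neighbor.  The permutation
p-value uses the add-one estimator

    p_spin = (#{|r_null| >= |r_obs|} + 1) / (n_perm + 1)

so p is always in [1/(n_perm + 1), 1].  Only the probe map is rotated; the
reference map stays fixed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .errors import ArgumentError, DataValidationError
from .mesh import TriangleMesh, VertexScalarMap

__all__ = [
    "SpinNull",
    "sample_rotation",
    "project_to_sphere",
    "spin_permutations",
    "spin_permute_map",
    "spin_pvalue",
]


@dataclass(frozen=True)
class SpinNull:
    """Null distribution and permutation p-value of one spin test."""

    n_perm: int
    r_obs: float
    r_null: np.ndarray
    p_spin: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "r_null", np.asarray(self.r_null, dtype=np.float64).ravel()
        )


def sample_rotation(rng: np.random.Generator) -> np.ndarray:
    """One Haar-uniform 3x3 rotation (orthogonal, determinant +1)."""
    return stats.special_ortho_group.rvs(3, random_state=rng)


def project_to_sphere(mesh: TriangleMesh) -> np.ndarray:
    """Radial projection of vertices onto the centroid-centered unit sphere.

    Valid for star-shaped surfaces (every ray from the centroid crosses the
    surface once).  Strongly non-star-shaped structures need externally
    computed spherical coordinates, which every spin function accepts
    directly.
    """
    centered = mesh.vertices - mesh.vertices.mean(axis=0)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if (norms == 0).any():
        raise DataValidationError(
            "a vertex coincides with the centroid; supply spherical "
            "coordinates from an external spherical registration"
        )
    return centered / norms


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ArgumentError("sphere coordinates must be (N, 3)")
    if not np.allclose(np.linalg.norm(coords, axis=1), 1.0, atol=1e-6):
        raise ArgumentError("sphere coordinates must have unit norm")
    return coords


def spin_permutations(
    sphere_coords: np.ndarray, n_perm: int, seed: int
) -> np.ndarray:
    """Precompute ``n_perm`` nearest-neighbor permutation index arrays.

    Row p holds, for each vertex i, the index of the original vertex nearest
    (in angle) to the rotated position of vertex i; applying ``map[row]``
    realizes one spin.  Euclidean (chordal) nearest neighbors on the unit
    sphere coincide with angular nearest neighbors; cKDTree breaks exact
    ties by lowest index.
    """
    coords = _check_coords(sphere_coords)
    if n_perm < 1:
        raise ArgumentError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    tree = cKDTree(coords)
    out = np.empty((n_perm, len(coords)), dtype=np.int64)
    for p in range(n_perm):
        rot = sample_rotation(rng)
        _, out[p] = tree.query(coords @ rot.T)
    return out


def spin_permute_map(
    vertex_map, sphere_coords: np.ndarray, rotation: np.ndarray
) -> np.ndarray:
    """Remap a vertex map through one rotation of its spherical projection."""
    values = (
        vertex_map.values
        if isinstance(vertex_map, VertexScalarMap)
        else np.asarray(vertex_map, dtype=np.float64).ravel()
    )
    coords = _check_coords(sphere_coords)
    if len(values) != len(coords):
        raise ArgumentError(
            f"map length {len(values)} != coordinate count {len(coords)}"
        )
    rotation = np.asarray(rotation, dtype=np.float64)
    if rotation.shape != (3, 3):
        raise ArgumentError("rotation must be a 3x3 matrix")
    tree = cKDTree(coords)
    _, nearest = tree.query(coords @ rotation.T)
    return values[nearest]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ArgumentError(f"unknown correlation method {method!r}")


def spin_pvalue(
    vertex_map,
    reference,
    sphere_coords: np.ndarray,
    n_perm: int = 10_000,
    method: str = "spearman",
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> SpinNull:
    """Spin-test significance of the map-reference spatial correlation.

    ``vertex_map`` is rotated and remapped ``n_perm`` times while
    ``reference`` stays fixed; precomputed ``permutations`` (from
    :func:`spin_permutations`) may be passed to amortize the rotation cost
    over many tests on the same sphere.
    """
    values = (
        vertex_map.values
        if isinstance(vertex_map, VertexScalarMap)
        else np.asarray(vertex_map, dtype=np.float64).ravel()
    )
    ref = (
        reference.values
        if isinstance(reference, VertexScalarMap)
        else np.asarray(reference, dtype=np.float64).ravel()
    )
    coords = _check_coords(sphere_coords)
    if not len(values) == len(ref) == len(coords):
        raise ArgumentError("map, reference, and coordinates must align")
    if values.std() == 0 or ref.std() == 0:
        raise DataValidationError("constant input map: correlation undefined")

    if permutations is None:
        permutations = spin_permutations(coords, n_perm, seed)
    else:
        permutations = np.asarray(permutations)
        if permutations.shape != (n_perm, len(values)):
            raise ArgumentError(
                f"permutations must be ({n_perm}, {len(values)})"
            )

    r_obs = abs(_corr(values, ref, method))
    permuted = values[permutations]  # (n_perm, N)
    if method == "spearman":
        x = stats.rankdata(permuted, axis=1)
        y = stats.rankdata(ref)
    else:
        x = permuted
        y = ref
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    r_null = (xc @ yc) / denom
    p = (int(np.count_nonzero(np.abs(r_null) >= r_obs)) + 1) / (n_perm + 1)
    return SpinNull(n_perm, r_obs, r_null, p, seed)
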