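"""Synthetic meshes, connectomes, null maps, and cohort tables.

Every analysis stage in the package can be exercised without MRI data: this
module generates inputs with *known planted structure* so recovery is
checkable.

- :func:`make_icosphere` / :func:`make_bumpy_surface` supply closed genus-0
  meshes with controllable folding (a stand-in for foliated cortex);
- :func:`make_planted_connectome` builds a connectivity matrix whose node
  profiles vary smoothly along a chosen geometric eigenmode, so the full
  parcellation -> affinity -> embedding -> GGC chain should recover that
  mode;
- :func:`make_smooth_null_maps` draws spatially autocorrelated maps with no
  preferred mode alignment, the input for spin-test calibration;
- :func:`make_cohort_volumes` emulates multi-individual region-volume
  tables.

All generators are pure functions of their arguments including the explicit
seed; no global RNG is ever touched.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh

from .errors import ArgumentError
from .eigen import EigenmodeSet, solve_eigenmodes
from .gradients import ConnectivityMatrix, Parcellation, spatial_parcellation
from .mesh import TriangleMesh

__all__ = [
    "PlantedConnectome",
    "make_icosphere",
    "make_bumpy_surface",
    "make_planted_connectome",
    "make_smooth_null_maps",
    "make_cohort_volumes",
]

# planted-connectome profile basis: 64 response-curve sample points with
# bandwidth 0.5 x sd(latent) -- wide enough that neighboring nodes share
# profile mass, narrow enough that the latent ordering dominates affinity
_PROFILE_GRID_SIZE = 64
_PROFILE_BANDWIDTH_FACTOR = 0.5


@dataclass(frozen=True)
class PlantedConnectome:
    """A connectome with a known latent gradient coordinate per node."""

    connectivity: ConnectivityMatrix
    latent: np.ndarray
    planted_mode_index: int
    noise_sd: float
    parcellation: Parcellation | None = None

    def __post_init__(self) -> None:
        latent = np.asarray(self.latent, dtype=np.float64).ravel()
        if len(latent) != self.connectivity.n_nodes:
            raise ArgumentError("latent must have one value per node")
        if not np.isfinite(latent).all():
            raise ArgumentError("latent contains non-finite values")
        object.__setattr__(self, "latent", latent)


def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Closed genus-0 icosphere with 10 * 4**s + 2 vertices."""
    if radius <= 0:
        raise ArgumentError("radius must be positive")
    if subdivisions < 0:
        raise ArgumentError("subdivisions must be >= 0")
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def _bump_pattern(unit_vertices: np.ndarray, frequency: int) -> np.ndarray:
    """Deterministic smooth bump pattern, |b| <= 1.

    A fixed product of cosine lobes along the three Cartesian axes (the
    restriction of a smooth triply periodic function to the sphere), with
    frequency ``f`` half-periods per unit length.  The small phase offsets
    break rotational and mirror symmetries so the perturbed sphere has a
    non-degenerate low spectrum; folding in all tangent directions keeps the
    gyrification index monotone in amplitude while the convex hull stays
    near the outer envelope.
    """
    x, y, z = unit_vertices.T
    f = np.pi * max(int(frequency), 1)
    return (
        np.cos(f * (x + 0.05))
        * np.cos(f * (y - 0.07))
        * np.cos(f * (z + 0.11))
    )


def make_bumpy_surface(
    subdivisions: int,
    amplitude: float,
    frequency: int = 6,
    seed: int = 0,
    radius: float = 1.0,
) -> TriangleMesh:
    """Radially perturbed icosphere: r(v) = R * (1 + amplitude * b(v)).

    ``b`` is the fixed cosine-lobe pattern of :func:`_bump_pattern`, so the
    mesh is fully deterministic; ``seed`` is accepted for interface symmetry
    with the other generators but does not influence the pattern.
    amplitude = 0 returns the unperturbed icosphere bitwise.
    """
    if not 0.0 <= amplitude < 1.0:
        raise ArgumentError(
            "amplitude must be in [0, 1) to avoid self-intersection"
        )
    base = make_icosphere(subdivisions, radius)
    if amplitude == 0.0:
        return base
    unit = base.vertices / radius
    r = radius * (1.0 + amplitude * _bump_pattern(unit, frequency))
    return TriangleMesh(unit * r[:, None], base.faces)


def make_planted_connectome(
    mesh: TriangleMesh,
    n_nodes: int,
    planted_mode_index: int,
    noise_sd: float,
    seed: int,
    modes: EigenmodeSet | None = None,
) -> PlantedConnectome:
    """Connectome whose node profiles track one geometric eigenmode.

    Mesh vertices are parcellated into ``n_nodes`` spatial clusters; the
    latent coordinate of each node is the node-mean of the chosen eigenmode.
    Node i's connectivity profile is a Gaussian response curve centered at
    latent_i over a fixed 64-point grid (bandwidth 0.5 x sd(latent)), plus
    N(0, noise_sd) noise; the matrix is P P^T clipped to >= 0 with zero
    diagonal, hence exactly symmetric.  Diffusion embedding of the
    noise-free matrix recovers the latent ordering.

    A precomputed ``modes`` set for the same mesh may be passed to skip the
    eigen-solve.
    """
    if planted_mode_index < 2:
        raise ArgumentError(
            "planted_mode_index must be >= 2 (Mode 1 is constant and "
            "unrecoverable)"
        )
    if n_nodes < 10:
        raise ArgumentError("n_nodes must be >= 10")
    if noise_sd < 0:
        raise ArgumentError("noise_sd must be nonnegative")
    if modes is None:
        modes = solve_eigenmodes(mesh, n_modes=max(planted_mode_index + 1, 10))
    if modes.n_vertices != mesh.n_vertices:
        raise ArgumentError("modes were computed on a different mesh")

    parc = spatial_parcellation(mesh.vertices, n_nodes, seed=seed)
    mode = modes.mode(planted_mode_index)
    latent = np.array(
        [mode[parc.labels == k].mean() for k in range(n_nodes)]
    )

    sd_latent = latent.std()
    bandwidth = _PROFILE_BANDWIDTH_FACTOR * sd_latent
    lo, hi = latent.min(), latent.max()
    grid = np.linspace(lo - bandwidth, hi + bandwidth, _PROFILE_GRID_SIZE)
    profiles = np.exp(-0.5 * ((grid[None, :] - latent[:, None]) / bandwidth) ** 2)
    rng = np.random.default_rng(seed)
    profiles = profiles + rng.normal(0.0, noise_sd, size=profiles.shape)

    counts = profiles @ profiles.T
    counts = np.clip(counts, 0.0, None)
    np.fill_diagonal(counts, 0.0)
    return PlantedConnectome(
        ConnectivityMatrix(counts), latent, planted_mode_index, noise_sd, parc
    )


def make_smooth_null_maps(
    modes: EigenmodeSet, n_maps: int, decay: float, seed: int
) -> np.ndarray:
    """Spatially autocorrelated null maps with no preferred mode alignment.

    Each map is sum_k w_k * mode_k over k >= 2 with w_k ~ N(0, exp(-decay*k))
    (standard deviation exp(-decay*k), k the 1-based mode number).  The
    exponential weight decay makes the maps smooth; because the weights are
    independent and zero-mean, no single mode is preferred beyond chance.

    Returns an (n_maps, N) array.
    """
    if n_maps <= 0:
        raise ArgumentError("n_maps must be positive")
    if decay <= 0:
        raise ArgumentError("decay must be positive")
    if modes.n_modes < 10:
        raise ArgumentError("need at least 10 modes for null maps")
    rng = np.random.default_rng(seed)
    k = np.arange(2, modes.n_modes + 1)  # exclude the constant Mode 1
    sd = np.exp(-decay * k)
    weights = rng.normal(0.0, 1.0, size=(n_maps, len(k))) * sd
    return weights @ modes.modes[:, 1:].T


def make_cohort_volumes(
    n_individuals: int,
    region_fractions: dict,
    scale_cv: float,
    seed: int,
    mean_total: float = 3252.0,
    fraction_jitter: float = 0.02,
    sex: tuple = (),
):
    """Per-individual regional volume table (pandas DataFrame, mm^3).

    Individual totals are lognormal with coefficient of variation
    ``scale_cv`` around ``mean_total`` (default: a tree-shrew-scale brain of
    3,252 mm^3); regional volumes split the total by Dirichlet-perturbed
    fractions with relative spread ``fraction_jitter`` (0 means exact
    fractions).  Columns are region labels; the optional ``sex`` tuple
    labels rows.
    """
    import pandas as pd

    if n_individuals < 2:
        raise ArgumentError("need at least 2 individuals")
    labels = list(region_fractions)
    fracs = np.array([region_fractions[k] for k in labels], dtype=np.float64)
    if abs(fracs.sum() - 1.0) > 1e-8:
        raise ArgumentError(
            f"region fractions must sum to 1 within 1e-8; got {fracs.sum()!r}"
        )
    if scale_cv < 0 or fraction_jitter < 0:
        raise ArgumentError("scale_cv and fraction_jitter must be nonnegative")
    rng = np.random.default_rng(seed)
    if scale_cv == 0:
        totals = np.full(n_individuals, mean_total)
    else:
        sigma2 = np.log1p(scale_cv**2)
        mu = np.log(mean_total) - 0.5 * sigma2
        totals = rng.lognormal(mu, np.sqrt(sigma2), size=n_individuals)
    if fraction_jitter == 0:
        parts = np.tile(fracs, (n_individuals, 1))
    else:
        conc = fracs / fraction_jitter**2
        parts = rng.dirichlet(conc, size=n_individuals)
    table = pd.DataFrame(
        totals[:, None] * parts,
        columns=labels,
        index=[f"N{i + 1:02d}" for i in range(n_individuals)],
    )
    if sex:
        if len(sex) != n_individuals:
            raise ArgumentError("sex labels must match n_individuals")
        table.attrs["sex"] = list(sex)
    return table
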