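"""Connectivity gradients: parcellation, affinity, diffusion-map embedding.

A structural connectome is reduced to a handful of continuous spatial axes
("gradients", SG1..SGG) in three steps:

1. nodes are defined by K-means clustering of 3D coordinates into spatially
   coherent micro-clusters;
2. an affinity matrix is built from the Pearson correlation between node
   connectivity profiles (after per-row sparsification), mapped through the
   normalized-angle kernel s = 1 - arccos(r)/pi so that similarities live in
   [0, 1] independently of connection magnitudes;
3. diffusion-map embedding of the affinity matrix yields the gradients,
   ordered by the eigenvalues of the Markov transition operator, with an
   explained-variance fraction per component.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .errors import ArgumentError, DataValidationError, NumericalError
from .eigen import fix_sign

__all__ = [
    "Parcellation",
    "ConnectivityMatrix",
    "AffinityMatrix",
    "GradientSet",
    "spatial_parcellation",
    "profile_affinity",
    "diffusion_embedding",
    "extremal_mask",
    "region_average_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Parcellation:
    """K-means node assignment of elements (vertices/voxels) to clusters."""

    labels: np.ndarray
    n_clusters: int
    centroids: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64).ravel()
        counts = np.bincount(labels, minlength=self.n_clusters)
        if (counts == 0).any():
            raise DataValidationError(
                f"empty clusters: {np.flatnonzero(counts == 0).tolist()}"
            )
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative node-by-node connection weights, zero diagonal."""

    counts: np.ndarray
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.float64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise DataValidationError(f"connectivity must be square; got {c.shape}")
        if not np.isfinite(c).all():
            i, j = np.argwhere(~np.isfinite(c))[0]
            raise DataValidationError(f"non-finite connectivity at ({i}, {j})")
        if not np.allclose(c, c.T, atol=1e-9, rtol=0.0):
            raise DataValidationError("connectivity matrix is not symmetric (tol 1e-9)")
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 0.0)
        if (c < 0).any():
            raise DataValidationError("connectivity contains negative weights")
        object.__setattr__(self, "counts", c)
        ids = self.node_ids
        if ids is None:
            ids = np.arange(c.shape[0])
        object.__setattr__(self, "node_ids", np.asarray(ids))

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class AffinityMatrix:
    """Normalized-angle similarities in [0, 1], unit diagonal."""

    similarities: np.ndarray
    sparsity_kept_fraction: float = 1.0

    def __post_init__(self) -> None:
        s = np.asarray(self.similarities, dtype=np.float64)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise DataValidationError("affinity must be square")
        if (s < -1e-12).any() or (s > 1 + 1e-12).any():
            raise DataValidationError("affinity values must lie in [0, 1]")
        object.__setattr__(self, "similarities", np.clip(s, 0.0, 1.0))

    @property
    def n_nodes(self) -> int:
        return self.similarities.shape[0]


@dataclass(frozen=True)
class GradientSet:
    """Diffusion-map components (K x G), eigenvalues, and variance fractions."""

    gradients: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.gradients.shape[1]

    def gradient(self, index: int) -> np.ndarray:
        """Return component by 1-based index (SG1 is the first)."""
        if not 1 <= index <= self.n_components:
            raise ArgumentError(f"gradient index {index} outside 1..{self.n_components}")
        return self.gradients[:, index - 1]


def spatial_parcellation(
    coordinates: np.ndarray, n_clusters: int, seed: int, n_init: int = 50
) -> Parcellation:
    """K-means micro-cluster nodes on raw 3D coordinates.

    Uses k-means++ initialization with ``n_init`` restarts; labels are
    deterministic given ``seed``.
    """
    coords = np.asarray(coordinates, dtype=np.float64)
    if coords.ndim != 2:
        raise ArgumentError("coordinates must be a 2D (E, 3) array")
    if n_clusters < 2:
        raise ArgumentError("need at least 2 clusters")
    if n_clusters >= len(coords):
        raise ArgumentError(
            f"n_clusters={n_clusters} must be < number of elements {len(coords)}"
        )
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=n_init,
        random_state=int(seed) % (2**32),
    ).fit(coords)
    return Parcellation(km.labels_, n_clusters, km.cluster_centers_)


def _sparsify_rows(matrix: np.ndarray, kept_fraction: float) -> np.ndarray:
    """Zero all but the largest ``kept_fraction`` entries of each row."""
    if not 0.0 < kept_fraction <= 1.0:
        raise ArgumentError("kept_fraction must be in (0, 1]")
    if kept_fraction == 1.0:
        return matrix.copy()
    k = int(np.ceil(kept_fraction * matrix.shape[1]))
    out = np.zeros_like(matrix)
    # threshold per row at the k-th largest value; ties above threshold kept
    idx = np.argpartition(matrix, -k, axis=1)[:, -k:]
    np.put_along_axis(out, idx, np.take_along_axis(matrix, idx, axis=1), axis=1)
    return out


def profile_affinity(
    connectivity: ConnectivityMatrix | np.ndarray, kept_fraction: float = 0.10
) -> AffinityMatrix:
    """Normalized-angle affinity between node connectivity profiles.

    Each connectivity row is sparsified to its top ``kept_fraction`` entries,
    rows are correlated pairwise (Pearson), and correlations are mapped
    through s = 1 - arccos(r)/pi.
    """
    if isinstance(connectivity, ConnectivityMatrix):
        counts = connectivity.counts
    else:
        counts = ConnectivityMatrix(np.asarray(connectivity)).counts
    if counts.shape[0] < 3:
        raise ArgumentError("need at least 3 nodes")
    profiles = _sparsify_rows(counts, kept_fraction)
    sd = profiles.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DataValidationError(
            f"constant connectivity profile for node(s) {flat[:5].tolist()}: "
            "cannot correlate"
        )
    r = np.corrcoef(profiles)
    s = 1.0 - np.arccos(np.clip(r, -1.0, 1.0)) / np.pi
    s = 0.5 * (s + s.T)
    return AffinityMatrix(s, kept_fraction)


def diffusion_embedding(
    affinity: AffinityMatrix | np.ndarray,
    n_components: int = 4,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Diffusion-map embedding of an affinity matrix.

    The affinity W is alpha-normalized, W' = D^-alpha W D^-alpha, and the
    Markov operator P = row-normalized W' is eigendecomposed (via the
    conjugate symmetric matrix, so the decomposition is exact and
    deterministic).  The trivial constant eigenvector is dropped; component k
    is psi_{k+1} scaled by lambda/(1 - lambda) when ``diffusion_time`` is 0
    (automatic multiscale weighting) or by lambda**t otherwise.  Explained
    variance is the eigenvalue share among the computed nontrivial
    components.
    """
    if isinstance(affinity, AffinityMatrix):
        w = affinity.similarities.copy()
    else:
        w = np.asarray(affinity, dtype=np.float64).copy()
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ArgumentError("affinity must be square")
        if (w < 0).any():
            raise DataValidationError("affinity must be nonnegative")
    if not np.allclose(w, w.T, atol=1e-9, rtol=0.0):
        raise DataValidationError("affinity must be symmetric")
    w = 0.5 * (w + w.T)
    n = w.shape[0]
    if not 1 <= n_components < n - 1:
        raise ArgumentError(f"n_components must be in [1, {n - 2}]")
    n_comp_graph, _ = connected_components(w > 0, directed=False)
    if n_comp_graph > 1:
        raise DataValidationError(
            f"affinity graph has {n_comp_graph} connected components; "
            "embedding requires a connected graph"
        )

    d = w.sum(axis=1)
    if alpha != 0.0:
        w = w / np.outer(d**alpha, d**alpha)
    d2 = w.sum(axis=1)
    # symmetric conjugate of the Markov operator: S = D^-1/2 W' D^-1/2
    inv_sqrt = 1.0 / np.sqrt(d2)
    s = w * np.outer(inv_sqrt, inv_sqrt)
    s = 0.5 * (s + s.T)
    try:
        eigval, eigvec = sla.eigh(s)
    except Exception as exc:
        raise NumericalError(f"dense eigendecomposition failed: {exc}") from exc
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    # right eigenvectors of P, normalized so the trivial one is constant 1
    psi = eigvec[:, order] * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]

    lam = eigval[1 : n_components + 1]
    vectors = psi[:, 1 : n_components + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    gradients = fix_sign(vectors * scale)
    nontrivial = eigval[1:]
    nontrivial = nontrivial[nontrivial > 0]
    explained = np.clip(lam, 0.0, None) / nontrivial.sum()
    return GradientSet(gradients, lam, explained)


def extremal_mask(values, fraction: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks for the top and bottom ``fraction`` of a map.

    Each mask flags ceil(fraction * N) entries; ties are broken by lowest
    index so the masks are reproducible.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if not 0.0 < fraction < 0.5:
        raise ArgumentError("fraction must be in (0, 0.5)")
    if np.ptp(vals) == 0:
        raise DataValidationError("constant map has no extremes")
    k = int(np.ceil(fraction * len(vals)))
    order = np.argsort(vals, kind="stable")
    top = np.zeros(len(vals), dtype=bool)
    bottom = np.zeros(len(vals), dtype=bool)
    bottom[order[:k]] = True
    # for the top mask, stable sort on -values keeps lowest-index ties first
    order_desc = np.argsort(-vals, kind="stable")
    top[order_desc[:k]] = True
    return top, bottom


def region_average_map(values, labels) -> dict:
    """Arithmetic mean of ``values`` per label, keyed by sorted label id."""
    vals = np.asarray(values, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if len(vals) != len(labels):
        raise ArgumentError(f"values ({len(vals)}) and labels ({len(labels)}) differ")
    out = {}
    for lab in np.unique(labels):
        sel = labels == lab
        if not sel.any():  # pragma: no cover - unique() guarantees nonempty
            logger.warning("label %r is empty; excluded from averages", lab)
            continue
        out[lab.item()] = float(vals[sel].mean())
    return out
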