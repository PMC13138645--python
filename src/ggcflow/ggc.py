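"""Geometry-gradient coupling (GGC).

GGC quantifies how strongly a connectivity gradient aligns with the
surface's geometric eigenmodes: for each gradient we compute the absolute
correlation against every mode ("correlation spectrum"), take the maximum
("peak GGC") together with the best mode index, and finally correlate peak
coupling strength with the gradient's explained variance across components.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import ArgumentError, DataValidationError
from .eigen import EigenmodeSet
from .gradients import GradientSet, region_average_map

__all__ = [
    "GGCResult",
    "correlation_spectrum",
    "peak_ggc",
    "ggc_variance_correlation",
    "ggc_analysis",
    "region_average_modes",
]


@dataclass(frozen=True)
class GGCResult:
    """Per-gradient coupling spectra, peaks, and the GGC-variance relation.

    ``spectra`` is (G, K) absolute correlations; ``peak_mode_index`` uses
    1-based mode numbering (Mode 1 is the constant and is excluded from the
    argmax by the zero convention).  ``ggc_variance_r`` is the Pearson
    correlation between peak |r| and explained variance across gradients
    (NaN when fewer than 3 gradients are available).
    """

    spectra: np.ndarray
    peak_abs_r: np.ndarray
    peak_mode_index: np.ndarray
    explained_variance: np.ndarray
    ggc_variance_r: float

    def to_dict(self) -> dict:
        d = asdict(self)
        return {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d.items()
        }


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ArgumentError(f"unknown correlation method {method!r}")


def correlation_spectrum(
    gradient: np.ndarray,
    modes: EigenmodeSet | np.ndarray,
    method: str = "pearson",
) -> np.ndarray:
    """Absolute correlation of one gradient map against every eigenmode.

    Entry k (0-based k = Mode k+1) is |corr(gradient, mode)|; the entry for
    the constant Mode 1 is 0 by convention, which keeps conventional mode
    numbering while excluding the contrast-free mode from any peak search.
    """
    g = np.asarray(gradient, dtype=np.float64).ravel()
    phi = modes.modes if isinstance(modes, EigenmodeSet) else np.asarray(modes)
    if phi.ndim != 2:
        raise ArgumentError("modes must be a 2D (N, K) array")
    if len(g) != phi.shape[0]:
        raise ArgumentError(
            f"gradient length {len(g)} != mode length {phi.shape[0]}"
        )
    if g.std() == 0:
        raise DataValidationError("constant gradient map cannot be correlated")
    out = np.zeros(phi.shape[1])
    for k in range(phi.shape[1]):
        col = phi[:, k]
        if k == 0 or col.std() == 0:
            out[k] = 0.0  # constant mode carries no spatial contrast
        else:
            out[k] = abs(_corr(g, col, method))
    return out


def peak_ggc(spectrum: np.ndarray) -> tuple[int, float]:
    """Peak coupling: (1-based mode index, |r|) with lowest-index ties."""
    spec = np.asarray(spectrum, dtype=np.float64).ravel()
    if spec.size < 2:
        raise ArgumentError("spectrum needs at least 2 modes")
    idx = int(np.argmax(spec))
    return idx + 1, float(spec[idx])


def ggc_variance_correlation(peak_abs_r, explained_variance) -> float:
    """Pearson correlation of peak GGC strength with explained variance."""
    r = np.asarray(peak_abs_r, dtype=np.float64).ravel()
    v = np.asarray(explained_variance, dtype=np.float64).ravel()
    if r.size != v.size:
        raise ArgumentError("vectors must have equal length")
    if r.size < 3:
        raise ArgumentError("need at least 3 gradients")
    if r.std() == 0 or v.std() == 0:
        raise DataValidationError("zero variance in peak |r| or explained variance")
    return float(stats.pearsonr(r, v).statistic)


def region_average_modes(modes: EigenmodeSet, labels) -> np.ndarray:
    """Average each eigenmode within parcellation labels (vertices -> nodes).

    Nodes are coarser than vertices, so averaging modes onto nodes is the
    well-posed direction for node-level gradient comparisons.  Rows follow
    sorted label id, matching :func:`region_average_map`.
    """
    label_order = sorted(region_average_map(modes.modes[:, 0], labels))
    out = np.empty((len(label_order), modes.n_modes))
    for k in range(modes.n_modes):
        means = region_average_map(modes.modes[:, k], labels)
        out[:, k] = [means[lab] for lab in label_order]
    return out


def ggc_analysis(
    gradients: GradientSet,
    modes: EigenmodeSet | np.ndarray,
    labels=None,
    method: str = "pearson",
) -> GGCResult:
    """Full GGC workup of a gradient set against an eigenmode basis.

    When ``labels`` is given, vertex-level modes are region-averaged onto the
    node set of the gradients first.
    """
    phi = modes
    if labels is not None:
        if not isinstance(modes, EigenmodeSet):
            raise ArgumentError("labels require an EigenmodeSet input")
        phi = region_average_modes(modes, labels)
    g_mat = gradients.gradients
    spectra = np.stack(
        [correlation_spectrum(g_mat[:, g], phi, method) for g in range(g_mat.shape[1])]
    )
    peaks = [peak_ggc(row) for row in spectra]
    peak_idx = np.array([p[0] for p in peaks], dtype=np.int64)
    peak_r = np.array([p[1] for p in peaks])
    if g_mat.shape[1] >= 3:
        ggc_var_r = ggc_variance_correlation(peak_r, gradients.explained_variance)
    else:
        ggc_var_r = float("nan")
    return GGCResult(
        spectra, peak_r, peak_idx, np.asarray(gradients.explained_variance), ggc_var_r
    )
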