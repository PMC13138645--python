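"""Cohort and cross-species volumetric statistics.

Covers the comparative-morphometry toolkit: relative regional volumes,
brain-to-body ratios, inter-individual coefficients of variation, a
normative confidence-interval check for under-represented groups, cerebellar
lobule standardization across species (17 enumerated lobules merged to 15
subregions, expanded to 30 hemispheric partitions), cross-species profile
similarity, and surface-area ratios.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, DataValidationError

__all__ = [
    "CEREBELLAR_LOBULES",
    "STANDARD_SUBREGIONS",
    "CohortVolumeTable",
    "SpeciesProfile",
    "relative_volumes",
    "brain_body_ratio",
    "coefficient_of_variation",
    "normative_ci_check",
    "merge_standard_subregions",
    "hemisphere_partitions",
    "cross_species_similarity",
    "surface_ratio",
]

# canonical cerebellar lobule enumeration (17 labels)
CEREBELLAR_LOBULES = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "SIM", "Par", "Cop", "Fl", "PFl", "Crus I", "Crus II",
)

# after merging I+II and IV+V: the 15 standardized cross-species subregions
STANDARD_SUBREGIONS = (
    "I-II", "III", "IV-V", "VI", "VII", "VIII", "IX", "X",
    "SIM", "Par", "Cop", "Fl", "PFl", "Crus I", "Crus II",
)

_MERGES = {"I-II": ("I", "II"), "IV-V": ("IV", "V")}


@dataclass
class CohortVolumeTable:
    """Per-individual regional volumes (mm^3) with per-individual sex."""

    volumes: pd.DataFrame  # rows: individuals, columns: region labels
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        vol = self.volumes
        if not isinstance(vol, pd.DataFrame):
            raise ArgumentError("volumes must be a pandas DataFrame")
        arr = vol.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise DataValidationError("all volumes must be positive and finite")
        if self.sex is not None and not self.sex.index.equals(vol.index):
            raise DataValidationError("sex index must match the volume table rows")

    @property
    def regions(self) -> list:
        return list(self.volumes.columns)


@dataclass
class SpeciesProfile:
    """One species' regional volumes or fractions plus body mass (g)."""

    species: str
    regions: dict = field(default_factory=dict)
    body_mass: float | None = None
    surface_areas: dict = field(default_factory=dict)


def relative_volumes(values: dict | pd.Series, denominator: float) -> dict:
    """Region volumes divided by a common denominator (e.g., total brain).

    When the regions form a full partition of the denominator the fractions
    sum to 1.
    """
    if denominator <= 0:
        raise ArgumentError("denominator volume must be positive")
    items = values.items() if hasattr(values, "items") else values
    return {k: float(v) / float(denominator) for k, v in items}


def brain_body_ratio(brain_volume: float, body_mass: float) -> float:
    """Brain volume (mm^3) over body mass (g)."""
    if brain_volume <= 0:
        raise ArgumentError("brain volume must be positive")
    if body_mass <= 0:
        raise ArgumentError("body mass must be positive")
    return brain_volume / body_mass


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) over the mean."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 2:
        raise ArgumentError("need at least 2 values for a CV")
    mean = x.mean()
    if mean == 0:
        raise ArgumentError("mean is zero; CV undefined")
    return float(x.std(ddof=1) / mean)


def normative_ci_check(
    reference_values, probe_value: float, level: float = 0.95
) -> dict:
    """Is a probe inside the reference group's t-based CI of the mean?

    Returns the interval bounds and the verdict ('inside'/'outside', strict
    exclusion).  Intended for normative screening of a small probe group
    (e.g., two females) against a larger reference group (nine males).
    """
    ref = np.asarray(reference_values, dtype=np.float64).ravel()
    if ref.size < 3:
        raise ArgumentError("reference group needs at least 3 values")
    if not 0 < level < 1:
        raise ArgumentError("level must be in (0, 1)")
    mean = ref.mean()
    sem = ref.std(ddof=1) / np.sqrt(ref.size)
    t = stats.t.ppf(0.5 * (1 + level), df=ref.size - 1)
    lo, hi = mean - t * sem, mean + t * sem
    verdict = "inside" if lo <= probe_value <= hi else "outside"
    return {"low": float(lo), "high": float(hi), "mean": float(mean),
            "verdict": verdict}


def merge_standard_subregions(lobule_values: dict) -> dict:
    """Merge the 17 enumerated lobules into 15 standardized subregions.

    Lobules I and II sum into 'I-II', IV and V into 'IV-V'; all other labels
    pass through.  Totals are conserved exactly.
    """
    missing = [lab for lab in CEREBELLAR_LOBULES if lab not in lobule_values]
    if missing:
        raise ArgumentError(f"missing cerebellar lobule label(s): {missing}")
    extras = set(lobule_values) - set(CEREBELLAR_LOBULES)
    if extras:
        raise ArgumentError(f"unexpected lobule label(s): {sorted(extras)}")
    out = {}
    for lab in STANDARD_SUBREGIONS:
        if lab in _MERGES:
            out[lab] = float(sum(lobule_values[p] for p in _MERGES[lab]))
        else:
            out[lab] = float(lobule_values[lab])
    return out


def hemisphere_partitions(
    standardized_labels=STANDARD_SUBREGIONS, hemispheres=("L", "R")
) -> list:
    """Expand standardized subregions into hemispheric partitions.

    Fixed ordering: hemispheres first (L before R), labels in the given
    canonical order within each hemisphere.  15 x 2 -> 30.
    """
    labels = list(standardized_labels)
    hemis = list(hemispheres)
    if not hemis:
        raise ArgumentError("hemisphere set must be non-empty")
    if len(set(labels)) != len(labels):
        raise ArgumentError("duplicate subregion labels")
    if len(set(hemis)) != len(hemis):
        raise ArgumentError("duplicate hemisphere labels")
    return [f"{h} {lab}" for h in hemis for lab in labels]


def cross_species_similarity(profile_a: dict, profile_b: dict) -> float:
    """Pearson correlation of two label-aligned fraction profiles."""
    keys_a, keys_b = set(profile_a), set(profile_b)
    if keys_a != keys_b:
        raise ArgumentError(
            f"label mismatch; symmetric difference: {sorted(keys_a ^ keys_b)}"
        )
    if len(keys_a) < 3:
        raise ArgumentError("need at least 3 shared labels")
    order = sorted(keys_a)
    a = np.array([profile_a[k] for k in order], dtype=np.float64)
    b = np.array([profile_b[k] for k in order], dtype=np.float64)
    return float(stats.pearsonr(a, b).statistic)


def surface_ratio(numerator_area: float, denominator_area: float) -> float:
    """100 x numerator / denominator, e.g., cerebellar over neocortical area."""
    if numerator_area <= 0:
        raise ArgumentError("numerator area must be positive")
    if denominator_area <= 0:
        raise ArgumentError("denominator area must be positive")
    return 100.0 * numerator_area / denominator_area
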