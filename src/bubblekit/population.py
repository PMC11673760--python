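"""Population statistics: size distributions and concentration estimates.

Per-image particle tables are pooled across the replicate images of a
sample (typically five per chamber); radii are histogrammed with a
square-root-of-N bin rule and the particle concentration is approximated as
the mean per-image count divided by the imaged volume (field-of-view area
times chamber height), scaled by the dilution factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np

from .segmentation import ParticleRecord

__all__ = [
    "SizeDistribution",
    "ConcentrationEstimate",
    "equiv_diameter",
    "bin_count",
    "build_distribution",
    "imaged_volume",
    "estimate_concentration",
]


@dataclass
class SizeDistribution:
    """Pooled radius histogram with sqrt(N) binning and summary moments."""

    radii_um: np.ndarray
    n_objects: int
    n_bins: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    mean_radius_um: float
    sd_radius_um: float


@dataclass
class ConcentrationEstimate:
    """Particles per mL derived from per-image counts and imaged volume."""

    mean_count_per_image: float
    imaged_volume_mL: float
    dilution_factor: float
    concentration_per_mL: float
    concentration_sd_per_mL: float
    n_images: int


def equiv_diameter(radius_um: float) -> float:
    """Equivalent-circle diameter from radius: the reported radius is
    multiplied by two (size standards are specified by diameter)."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    return 2.0 * radius_um


def bin_count(n_objects: int) -> int:
    """Histogram bin count: round(sqrt(N)), nearest integer with halves
    away from zero, floor of 1."""
    if n_objects < 1:
        raise ValueError("need at least one object to build a distribution")
    return max(1, int(np.floor(np.sqrt(n_objects) + 0.5)))


def _pool_radii(records_by_image: Iterable[Sequence[ParticleRecord]]) -> np.ndarray:
    radii = [
        rec.equiv_radius_um for records in records_by_image for rec in records
    ]
    return np.asarray(radii, dtype=np.float64)


def build_distribution(records_by_image: Iterable[Sequence[ParticleRecord]]) -> SizeDistribution:
    """Pool radii across images and histogram them with sqrt(N) bins.

    The histogram spans [min, max] of the pooled radii, each bin closed on
    the left and the last bin closed on both edges, so every object lands
    in exactly one bin.
    """
    radii = _pool_radii(records_by_image)
    if radii.size == 0:
        raise ValueError("no particle records: cannot build a size distribution")
    n = int(radii.size)
    n_bins = bin_count(n)
    lo, hi = float(radii.min()), float(radii.max())
    if hi <= lo:  # monodisperse to machine precision: center a unit-width range
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(radii, bins=n_bins, range=(lo, hi))
    return SizeDistribution(
        radii_um=radii,
        n_objects=n,
        n_bins=n_bins,
        bin_edges=edges,
        bin_counts=counts,
        mean_radius_um=float(radii.mean()),
        sd_radius_um=float(radii.std(ddof=1)) if n > 1 else 0.0,
    )


def imaged_volume(fov_px: Sequence[int], pixel_size_um: float, chamber_height_um: float) -> float:
    """Volume of sample imaged in one frame, in mL.

    rows x cols x pixel_size^2 gives the field-of-view area in um^2; times
    the chamber height in um gives um^3; 1 um^3 = 1e-12 mL.
    """
    rows, cols = fov_px
    if rows <= 0 or cols <= 0 or pixel_size_um <= 0 or chamber_height_um <= 0:
        raise ValueError("field of view, pixel size and chamber height must be positive")
    volume_um3 = rows * cols * pixel_size_um**2 * chamber_height_um
    return volume_um3 * 1e-12


def estimate_concentration(
    per_image_counts: Sequence[int],
    volume_mL: float,
    dilution_factor: float = 1.0,
) -> ConcentrationEstimate:
    """Concentration = mean per-image count / imaged volume x dilution.

    The spread is the sample SD of the per-image counts propagated through
    the same division, i.e. the replicate-to-replicate variability of the
    estimate (SD, not SEM).
    """
    counts = np.asarray(per_image_counts, dtype=np.float64)
    if counts.size < 1:
        raise ValueError("need at least one image")
    if volume_mL <= 0:
        raise ValueError("imaged volume must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    mean_count = float(counts.mean())
    if counts.size == 1:
        warnings.warn("single image: concentration SD is undefined, reporting 0", stacklevel=2)
        sd_count = 0.0
    else:
        sd_count = float(counts.std(ddof=1))
    return ConcentrationEstimate(
        mean_count_per_image=mean_count,
        imaged_volume_mL=volume_mL,
        dilution_factor=dilution_factor,
        concentration_per_mL=mean_count / volume_mL * dilution_factor,
        concentration_sd_per_mL=sd_count / volume_mL * dilution_factor,
        n_images=int(counts.size),
    )
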