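"""Annular peritumoral band construction and deformation-magnitude statistics.

The brain-around-tumor (BAT) region is partitioned by Euclidean distance d
from the tumor infiltrating edge into 12 cumulative annular bands of 5 mm
width (0 < d <= 5k mm, k = 1..12), each band inclusive of all inner margins.
Five statistics of the per-voxel deformation magnitude are aggregated per
band — mean (M), median (MD), standard deviation (STD), skewness (SK) and
excess kurtosis (K) — giving the 60-feature deformation-heterogeneity
descriptor.

Moment conventions: population (biased) central moments, Fisher excess
kurtosis. A zero-variance band reports SK = K = 0 (degenerate convention,
so constant phantoms remain well-defined); an empty band reports NaN for
all five statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "STAT_NAMES",
    "BAND_WIDTH_MM",
    "N_BANDS",
    "canonical_feature_names",
    "DistanceMap",
    "BandSet",
    "BandStatistics",
    "compute_distance_map",
    "make_bands",
    "band_statistics",
    "extract_features",
]

STAT_NAMES = ("M", "MD", "STD", "SK", "K")
BAND_WIDTH_MM = 5.0
N_BANDS = 12


def canonical_feature_names(
    width_mm: float = BAND_WIDTH_MM, n_bands: int = N_BANDS
) -> list[str]:
    """Stat-major canonical column order: M_5..M_60, MD_5.., STD_5.., SK_5.., K_5..K_60."""
    dists = [int(round(width_mm * (k + 1))) for k in range(n_bands)]
    return [f"{stat}_{d}" for stat in STAT_NAMES for d in dists]


@dataclass
class DistanceMap:
    """Euclidean distance (mm) to the nearest tumor voxel, on the BAT region.

    ``d`` holds the anisotropic-spacing distance transform of the tumor
    complement; ``valid`` marks brain-and-not-tumor voxels, the only region
    where the map is meaningful.
    """

    d: np.ndarray
    valid: np.ndarray
    spacing_mm: tuple[float, float, float]


@dataclass
class BandSet:
    """Cumulative annular masks keyed by outer distance in mm (5, 10, ... 60)."""

    bands: dict[int, np.ndarray]
    cumulative: bool
    width_mm: float

    @property
    def outer_boundaries_mm(self) -> list[int]:
        return sorted(self.bands)


@dataclass
class BandStatistics:
    M: float
    MD: float
    STD: float
    SK: float
    K: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.M, self.MD, self.STD, self.SK, self.K)


def compute_distance_map(
    tumor_mask: np.ndarray,
    brain_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
) -> DistanceMap:
    """Distance from the tumor infiltrating edge, in physical mm.

    Distances are measured to the nearest tumor voxel (mask-based, no
    sub-voxel surface model) under the anisotropic voxel spacing.
    """
    tumor = np.asarray(tumor_mask, dtype=bool)
    brain = np.asarray(brain_mask, dtype=bool)
    if tumor.shape != brain.shape:
        raise ValueError("tumor and brain masks must share a grid")
    if not tumor.any():
        raise ValueError("empty tumor mask: no infiltrating edge to measure from")
    if not (brain & ~tumor).any():
        raise ValueError("tumor covers the whole brain mask: no BAT region")
    d = ndimage.distance_transform_edt(~tumor, sampling=spacing_mm)
    return DistanceMap(d=d, valid=brain & ~tumor, spacing_mm=tuple(spacing_mm))


def make_bands(
    dmap: DistanceMap,
    width_mm: float = BAND_WIDTH_MM,
    n_bands: int = N_BANDS,
    cumulative: bool = True,
) -> BandSet:
    """Build the annular band masks {0 < d <= k*width} on the BAT region.

    With ``cumulative=False`` the bands are the disjoint shells
    ((k-1)*width, k*width] instead; their union equals the outermost
    cumulative band.
    """
    if width_mm <= 0 or n_bands < 1:
        raise ValueError("width_mm must be > 0 and n_bands >= 1")
    bands: dict[int, np.ndarray] = {}
    inside = dmap.valid & (dmap.d > 0)
    for k in range(1, n_bands + 1):
        outer = k * width_mm
        m = inside & (dmap.d <= outer)
        if not cumulative:
            m &= dmap.d > (k - 1) * width_mm
        bands[int(round(outer))] = m
    empties = [o for o, m in bands.items() if not m.any()]
    if empties:
        warnings.warn(f"empty band(s) at outer distance {empties} mm", stacklevel=2)
    return BandSet(bands=bands, cumulative=cumulative, width_mm=width_mm)


def _moment_statistics(values: np.ndarray) -> BandStatistics:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return BandStatistics(*(float("nan"),) * 5)
    mean = float(v.mean())
    med = float(np.median(v))
    c = v - mean
    m2 = float(np.mean(c**2))
    std = float(np.sqrt(m2))
    if m2 == 0.0:
        return BandStatistics(mean, med, 0.0, 0.0, 0.0)
    m3 = float(np.mean(c**3))
    m4 = float(np.mean(c**4))
    return BandStatistics(mean, med, std, m3 / m2**1.5, m4 / m2**2 - 3.0)


def band_statistics(magnitude: np.ndarray, band: np.ndarray) -> BandStatistics:
    """Five aggregate statistics of the deformation magnitudes in one band."""
    mag = np.asarray(magnitude, dtype=float)
    band = np.asarray(band, dtype=bool)
    if mag.shape != band.shape:
        raise ValueError("magnitude map and band mask must share a grid")
    return _moment_statistics(mag[band])


def extract_features(
    magnitude: np.ndarray,
    tumor_mask: np.ndarray,
    brain_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    width_mm: float = BAND_WIDTH_MM,
    n_bands: int = N_BANDS,
    cumulative: bool = True,
) -> pd.Series:
    """The 60-feature deformation descriptor of one subject.

    Chains distance map -> cumulative bands -> 5 statistics x 12 bands and
    returns a Series in the canonical stat-major column order.
    """
    mag = np.asarray(magnitude, dtype=float)
    if mag.shape != np.asarray(tumor_mask).shape:
        raise ValueError("magnitude map and masks must share a grid")
    dmap = compute_distance_map(tumor_mask, brain_mask, spacing_mm)
    bset = make_bands(dmap, width_mm=width_mm, n_bands=n_bands, cumulative=cumulative)
    stats = {outer: band_statistics(mag, bset.bands[outer]) for outer in bset.outer_boundaries_mm}
    names = canonical_feature_names(width_mm, n_bands)
    values = []
    for name in names:
        stat, dist = name.rsplit("_", 1)
        values.append(getattr(stats[int(dist)], stat))
    return pd.Series(values, index=names, dtype=float)
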