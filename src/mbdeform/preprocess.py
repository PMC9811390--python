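"""Bias-field correction and cohort-wide intensity standardization.

Gd-T1w inputs are first corrected for the smooth multiplicative intensity
inhomogeneity of MR acquisition, then mapped onto a cohort histogram
template (Nyul-style piecewise-linear landmark matching) so that
intensities are comparable across scanners before registration.

The native bias correction fits a low-order 3-D polynomial to the in-mask
log-intensities and divides it out (an N4-style multiplicative model
without the B-spline hierarchy); any external corrector honoring the same
contract — smooth multiplicative field removed, in-mask mean preserved —
can be substituted upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rng import stream
from .grid import ImageVolume

__all__ = [
    "DEFAULT_LANDMARK_PERCENTILES",
    "HistogramTemplate",
    "correct_bias",
    "build_histogram_template",
    "standardize_intensity",
]

#: Standard decile landmarks with 1/99 tails, the usual choice for
#: piecewise-linear histogram standardization.
DEFAULT_LANDMARK_PERCENTILES: tuple[float, ...] = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


def _polynomial_design(shape: tuple[int, int, int], order: int, mask: np.ndarray) -> np.ndarray:
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    xs = np.meshgrid(*coords, indexing="ij")
    cols = []
    for px in range(order + 1):
        for py in range(order + 1 - px):
            for pz in range(order + 1 - px - py):
                cols.append((xs[0] ** px * xs[1] ** py * xs[2] ** pz)[mask])
    return np.stack(cols, axis=1)


def correct_bias(volume: ImageVolume, mask: np.ndarray, order: int = 3) -> ImageVolume:
    """Remove a smooth multiplicative bias field estimated from log-intensities.

    A polynomial of the given order is least-squares fitted to the in-mask
    log-intensities; the volume is divided by the exponentiated fit
    (normalized to unit geometric mean in the mask) and rescaled so the
    in-mask arithmetic mean is preserved. Geometry (shape, spacing) is
    unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask and volume must share a grid")
    if not mask.any():
        raise ValueError("empty brain mask")
    data = np.asarray(volume.data, dtype=float)
    in_mask = data[mask]
    if np.all(in_mask == 0):
        raise ValueError("all-zero volume: nothing to correct")

    n_coef = sum(1 for px in range(order + 1) for py in range(order + 1 - px)
                 for _ in range(order + 1 - px - py))
    if mask.sum() < 2 * n_coef:
        raise ValueError(
            f"mask too small for order-{order} bias fit ({int(mask.sum())} voxels, "
            f"{n_coef} coefficients)"
        )

    floor = max(np.abs(in_mask).max() * 1e-6, np.finfo(float).tiny)
    log_i = np.log(np.maximum(data, floor))
    design = _polynomial_design(volume.shape, order, mask)
    coef, *_ = np.linalg.lstsq(design, log_i[mask], rcond=None)

    full = _polynomial_design(volume.shape, order, np.ones(volume.shape, dtype=bool))
    log_field = (full @ coef).reshape(volume.shape)
    log_field -= log_field[mask].mean()  # unit geometric mean in mask
    corrected = data / np.exp(log_field)

    mean_in = in_mask.mean()
    mean_out = corrected[mask].mean()
    if mean_out != 0:
        corrected *= mean_in / mean_out
    return volume.with_data(corrected)


@dataclass
class HistogramTemplate:
    """Cohort intensity landmarks: percentiles and their template intensities."""

    landmark_percentiles: tuple[float, ...]
    landmark_intensities: tuple[float, ...]
    n_contributing: int

    def __post_init__(self) -> None:
        p = np.asarray(self.landmark_percentiles, dtype=float)
        v = np.asarray(self.landmark_intensities, dtype=float)
        if p.size != v.size or p.size < 2:
            raise ValueError("need matching percentile/intensity lists of length >= 2")
        if np.any(p <= 0) or np.any(p >= 100) or np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly increasing within (0, 100)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("landmark intensities must be strictly increasing")
        if self.n_contributing < 1:
            raise ValueError("n_contributing must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "landmark_percentiles": list(self.landmark_percentiles),
                    "landmark_intensities": list(self.landmark_intensities),
                    "n_contributing": self.n_contributing,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HistogramTemplate":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["landmark_percentiles"]),
            tuple(d["landmark_intensities"]),
            int(d["n_contributing"]),
        )


def build_histogram_template(
    volumes: list[ImageVolume],
    masks: list[np.ndarray],
    fraction: float = 0.1,
    seed: int = 0,
    percentiles: tuple[float, ...] = DEFAULT_LANDMARK_PERCENTILES,
) -> HistogramTemplate:
    """Average landmark intensities over a random ~``fraction`` of the cohort.

    ceil(fraction * n) volumes are drawn (raised to 2 if the fraction
    selects fewer, since a one-volume "template" is just that volume); the
    template landmark at each percentile is the arithmetic mean of the
    selected volumes' in-mask percentiles.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(volumes) != len(masks):
        raise ValueError("volumes and masks must pair up")
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes to build a template")
    n_sel = max(2, int(np.ceil(fraction * len(volumes))))
    rng = stream(seed, "histogram-template")
    idx = rng.choice(len(volumes), size=min(n_sel, len(volumes)), replace=False)
    pcts = np.asarray(percentiles, dtype=float)
    landmarks = np.mean(
        [np.percentile(np.asarray(volumes[i].data)[np.asarray(masks[i], bool)], pcts) for i in idx],
        axis=0,
    )
    if np.any(np.diff(landmarks) <= 0):
        raise ValueError("degenerate template: landmark intensities not strictly increasing")
    return HistogramTemplate(tuple(pcts), tuple(landmarks), len(idx))


def standardize_intensity(
    volume: ImageVolume, mask: np.ndarray, template: HistogramTemplate
) -> ImageVolume:
    """Piecewise-linear landmark mapping onto the template distribution.

    The volume's in-mask intensities at the template percentiles are mapped
    onto the template landmark intensities, interpolating linearly between
    landmarks and extrapolating linearly beyond the first/last landmark
    with the adjacent segment's slope. The map is monotone nondecreasing.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask and volume must share a grid")
    data = np.asarray(volume.data, dtype=float)
    src = np.percentile(data[mask], template.landmark_percentiles)
    if np.all(np.diff(src) == 0):
        raise ValueError("constant in-mask intensities: cannot standardize")
    dst = np.asarray(template.landmark_intensities, dtype=float)
    # collapse duplicate source landmarks so np.interp stays well-defined
    keep = np.concatenate([[True], np.diff(src) > 0])
    src_u, dst_u = src[keep], dst[keep]
    mapped = np.interp(data, src_u, dst_u)
    lo_slope = (dst_u[1] - dst_u[0]) / (src_u[1] - src_u[0])
    hi_slope = (dst_u[-1] - dst_u[-2]) / (src_u[-1] - src_u[-2])
    below = data < src_u[0]
    above = data > src_u[-1]
    mapped[below] = dst_u[0] + lo_slope * (data[below] - src_u[0])
    mapped[above] = dst_u[-1] + hi_slope * (data[above] - src_u[-1])
    return volume.with_data(mapped)
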