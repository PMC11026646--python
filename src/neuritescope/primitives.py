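"""Shared calibrated image operators.

The fluorescence pipelines all reduce to the same handful of primitives:
background flattening with a white top-hat, histogram thresholding (Otsu or
Triangle), connected-component extraction with per-component shape
descriptors, and Fiji-style particle analysis with physical size bounds.
All physical parameters are given in micrometres and converted through the
image calibration, because the cut-offs that matter scientifically
(5 um^2 components, the 15 um overlap limit) are physical quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, morphology

from .images import CalibratedImage, ConstantImageError

#: number of histogram bins used for automatic thresholds (Fiji default)
HISTOGRAM_BINS = 256


@dataclass(frozen=True)
class Component:
    """One connected component of a binary mask, with physical descriptors."""

    label: int
    pixel_count: int
    area_um2: float
    eccentricity: float
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (row_start, col_start, row_stop, col_stop), half-open
    coords: np.ndarray | None = None


def tophat(img: CalibratedImage, radius_um: float) -> CalibratedImage:
    """White top-hat with a disc structuring element of physical radius.

    Removes smooth background (anything wider than the disc) while keeping
    compact bright features; a flat image maps to zero everywhere and the
    output never exceeds the input.
    """
    if not radius_um > 0:
        raise ValueError("radius_um must be positive")
    radius_px = int(round(radius_um / img.pixel_size))
    if radius_px < 1:
        raise ValueError(
            f"top-hat radius {radius_um} um is below one pixel at {img.pixel_size} um/px"
        )
    out = morphology.white_tophat(img.pixels, footprint=morphology.disk(radius_px))
    # guard against tiny negative round-off from the float morphology
    return CalibratedImage(np.clip(out, 0, None), img.pixel_size)


def threshold(img: CalibratedImage, method: str = "otsu") -> tuple[np.ndarray, float]:
    """Automatic histogram threshold; returns (foreground mask, threshold).

    ``otsu`` maximises the between-class variance of the 256-bin gray-level
    histogram; ``triangle`` maximises the perpendicular distance between the
    histogram and the line joining its peak to its far end.  Foreground is
    the set of pixels strictly above the threshold.
    """
    pixels = img.pixels
    if pixels.max() == pixels.min():
        raise ConstantImageError("cannot threshold a constant image (no two classes)")
    if method == "otsu":
        t = filters.threshold_otsu(pixels, nbins=HISTOGRAM_BINS)
    elif method == "triangle":
        t = filters.threshold_triangle(pixels, nbins=HISTOGRAM_BINS)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return pixels > t, float(t)


def connected_components(
    mask: np.ndarray,
    pixel_size: float,
    connectivity: int = 8,
    keep_coords: bool = False,
) -> list[Component]:
    """Label a binary mask and compute per-component physical descriptors.

    Eccentricity is that of the ellipse with matching second central
    moments (0 for a disc, approaching 1 for a line).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    out = []
    for rp in measure.regionprops(labels):
        out.append(
            Component(
                label=int(rp.label),
                pixel_count=int(rp.area),
                area_um2=float(rp.area) * pixel_size**2,
                eccentricity=float(rp.eccentricity),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=tuple(int(v) for v in rp.bbox),
                coords=rp.coords if keep_coords else None,
            )
        )
    return out


@dataclass(frozen=True)
class ParticleStats:
    count: int
    sizes_um2: np.ndarray
    total_area_um2: float


def particle_analysis(
    mask: np.ndarray,
    pixel_size: float,
    min_size_um2: float = 0.0,
    max_size_um2: float = np.inf,
) -> ParticleStats:
    """Count 8-connected particles with area inside [min_size, max_size] um^2."""
    if min_size_um2 > max_size_um2:
        raise ValueError("min_size_um2 must not exceed max_size_um2")
    comps = connected_components(mask, pixel_size, connectivity=8)
    sizes = np.array(
        [c.area_um2 for c in comps if min_size_um2 <= c.area_um2 <= max_size_um2],
        dtype=np.float64,
    )
    return ParticleStats(count=sizes.size, sizes_um2=sizes, total_area_um2=float(sizes.sum()))
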