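"""Detection and counting of TMRM-labelled mitochondria.

The detection chain is: white top-hat (background flattening) -> Otsu
threshold -> salt-noise removal by a small binary median -> 8-connected
component extraction -> artifact rejection, discarding components whose area
exceeds 5 um^2 or whose eccentricity exceeds 0.995 (large elongated edge
artifacts).  The count is the number of surviving components and each
mitochondrion's size is its as-detected pixel count times the pixel area.

Also here: counts over paired timepoints, z-stack height measures, and the
two-channel foreground area ratio.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .images import CalibratedImage, ConstantImageError, ZStack
from .primitives import Component, connected_components, threshold, tophat
from .roi import TunnelROI


@dataclass(frozen=True)
class MitoConfig:
    tophat_radius_um: float = 2.0   # larger than any mitochondrion
    smooth_sigma_px: float = 1.0    # PSF-matched pre-smoothing for detection
    threshold_method: str = "robust"  # 'robust' (median + n*MAD) or 'otsu'
    threshold_nsigma: float = 4.25
    min_peak_nsigma: float = 5.0    # a component must contain one pixel this
                                    # bright; noise clusters hug the footprint
                                    # threshold, real puncta peak far above it
    size_mode: str = "fwhm"         # 'fwhm' (kernel-corrected) or 'detected'
    min_footprint_px: int = 2       # kills single-pixel noise specks
    max_area_um2: float = 5.0       # artifact rejection: size rule
    max_eccentricity: float = 0.995  # artifact rejection: elongation rule
    eccentricity_min_px: int = 10   # smallest footprint with a meaningful
                                    # ellipse fit; the elongation rule exists
                                    # for large edge artifacts, not puncta
    median_size_px: int = 0         # binary median for salt noise (use with
                                    # smooth_sigma_px=0; the matched filter
                                    # already suppresses isolated noise)
    min_slice_area_um2: float = 1.0  # per-slice signal criterion for heights


@dataclass(frozen=True)
class MitoDetection:
    components: list[Component]
    n_rejected_area: int
    n_rejected_eccentricity: int
    tunnel_id: str | None = None
    frame_index: int | None = None

    @property
    def count(self) -> int:
        return len(self.components)

    @property
    def sizes_um2(self) -> np.ndarray:
        return np.array([c.area_um2 for c in self.components])


def _fwhm_size_um2(
    flattened: np.ndarray,
    comp,
    background: float,
    kernel_sigma_px: float,
    pixel_size: float,
) -> float:
    """Half-maximum footprint of one punctum, corrected for the detection
    smoothing kernel.

    The footprint is the area inside the sub-pixel half-maximum contour
    (marching squares) on the smoothed image; a Gaussian blob smoothed by a
    Gaussian kernel gains exactly ``2 * pi * sigma_kernel^2 * ln 2`` pixels
    of half-maximum area, which is subtracted again, so the estimate is
    unbiased for diffraction-limited puncta.
    """
    r0, c0, r1, c1 = comp.bbox
    pad = 4
    rs, cs = max(r0 - pad, 0), max(c0 - pad, 0)
    win = flattened[rs : r1 + pad, cs : c1 + pad]
    peak_flat = int(np.argmax(win))
    peak_rc = np.unravel_index(peak_flat, win.shape)
    peak = float(win[peak_rc])
    if peak <= background:
        return comp.pixel_count * pixel_size**2
    half = background + 0.5 * (peak - background)
    area_px = None
    for contour in measure.find_contours(win, half):
        if not np.array_equal(contour[0], contour[-1]):
            continue
        if measure.points_in_poly([peak_rc], contour)[0]:
            y, x = contour[:, 0], contour[:, 1]
            area_px = 0.5 * abs(np.dot(y, np.roll(x, 1)) - np.dot(x, np.roll(y, 1)))
            break
    if area_px is None:  # open contour at the window edge: fall back
        area_px = float((win >= half).sum())
    correction = 2.0 * np.pi * kernel_sigma_px**2 * np.log(2.0)
    return max(area_px - correction, 1.0) * pixel_size**2


def detect_mitochondria(
    frame: CalibratedImage,
    cfg: MitoConfig = MitoConfig(),
    tunnel_id: str | None = None,
    frame_index: int | None = None,
) -> MitoDetection:
    """Run the detection chain on one calibrated frame.

    The frame is smoothed with a PSF-sized Gaussian (matched filter),
    background-flattened with a white top-hat, and binarised.  The default
    threshold is noise-referenced (image median plus ``threshold_nsigma``
    robust SDs): puncta occupy a few percent of a tunnel frame, far below
    the class balance a gray-level histogram split needs, so Otsu drifts
    into the noise there; it remains available as ``threshold_method``
    for high-contrast data.  Sizes are half-maximum footprints corrected
    for the smoothing kernel by default (``size_mode='detected'`` reports
    raw as-detected pixel counts instead, which depend on where the global
    threshold happens to sit).  A constant frame yields zero detections
    rather than an error.
    """
    # pad with the median before filtering: reflect-style padding would
    # double the noise variance along the frame border and seed spurious
    # border detections
    pad = int(np.ceil(cfg.tophat_radius_um / frame.pixel_size + 4 * cfg.smooth_sigma_px)) + 1
    pixels = np.pad(frame.pixels, pad, mode="constant",
                    constant_values=float(np.median(frame.pixels)))
    if cfg.smooth_sigma_px > 0:
        pixels = ndimage.gaussian_filter(pixels, cfg.smooth_sigma_px)
    flattened = tophat(CalibratedImage(pixels, frame.pixel_size), cfg.tophat_radius_um)
    flattened = CalibratedImage(flattened.pixels[pad:-pad, pad:-pad], frame.pixel_size)
    if cfg.threshold_method == "otsu":
        try:
            mask, _ = threshold(flattened, "otsu")
        except ConstantImageError:
            return MitoDetection([], 0, 0, tunnel_id, frame_index)
    elif cfg.threshold_method == "robust":
        # background level and noise scale from the lower tail only (the
        # q10/q25 quantile pair): bright objects lift the median and the
        # upper tail but never the lower one
        q10, q25 = np.percentile(flattened.pixels, [10, 25])
        sigma = (q25 - q10) / 0.6078
        med = float(q25 + 0.6745 * sigma)
        if sigma == 0 and flattened.pixels.max() == med:
            return MitoDetection([], 0, 0, tunnel_id, frame_index)
        sigma = max(sigma, 1e-12)
        mask = flattened.pixels > med + cfg.threshold_nsigma * sigma
        if cfg.min_peak_nsigma > cfg.threshold_nsigma:
            peak_level = med + cfg.min_peak_nsigma * sigma
            labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), np.uint8))
            if n_lab:
                peaks = ndimage.maximum(flattened.pixels, labels, np.arange(1, n_lab + 1))
                keep = np.concatenate(([False], peaks >= peak_level))
                mask = keep[labels]
    else:
        raise ValueError(f"unknown threshold_method {cfg.threshold_method!r}")
    if cfg.median_size_px and cfg.median_size_px > 1:
        mask = ndimage.median_filter(mask, size=cfg.median_size_px)
    comps = connected_components(mask, frame.pixel_size, connectivity=8)
    background = float(np.median(flattened.pixels))
    kept, rej_area, rej_ecc = [], 0, 0
    for c in comps:
        if c.pixel_count < cfg.min_footprint_px:
            continue
        if cfg.size_mode == "fwhm":
            size = _fwhm_size_um2(flattened.pixels, c, background,
                                  cfg.smooth_sigma_px, frame.pixel_size)
            c = replace(c, area_um2=size)
        if c.area_um2 > cfg.max_area_um2:
            rej_area += 1
        elif c.pixel_count >= cfg.eccentricity_min_px and c.eccentricity > cfg.max_eccentricity:
            rej_ecc += 1
        else:
            kept.append(c)
    return MitoDetection(kept, rej_area, rej_ecc, tunnel_id, frame_index)


def count_over_timepoints(
    timepoint_images: Mapping[str, Sequence[CalibratedImage]],
    rois: Sequence[TunnelROI],
    cfg: MitoConfig = MitoConfig(),
) -> pd.DataFrame:
    """Per-tunnel mitochondria counts across timepoints, for paired stats.

    ``timepoint_images`` maps each timepoint label to one frame per imaging
    field; the same tunnel ROIs are applied at every timepoint (the same
    area of the same tunnels is imaged each time).  Returns a long table
    (tunnel, timepoint, count); pivot on tunnel for paired comparisons.
    """
    rows = []
    for timepoint, images in timepoint_images.items():
        for img_idx, image in enumerate(images):
            for roi in rois:
                det = detect_mitochondria(roi.crop_image(image), cfg, roi.tunnel_id)
                rows.append(dict(
                    timepoint=timepoint, image=img_idx,
                    tunnel=f"{img_idx}/{roi.tunnel_id}", count=det.count,
                ))
    return pd.DataFrame(rows, columns=["timepoint", "image", "tunnel", "count"])


def paired_counts(table: pd.DataFrame, baseline: str, followup: str) -> pd.DataFrame:
    """Wide per-tunnel pairs (baseline, followup, difference)."""
    wide = table.pivot_table(index="tunnel", columns="timepoint", values="count")
    out = wide[[baseline, followup]].dropna().astype(int)
    out["difference"] = out[followup] - out[baseline]
    return out.reset_index()


@dataclass(frozen=True)
class HeightResult:
    height_um: float
    first_slice: int | None
    last_slice: int | None
    per_slice_area_um2: np.ndarray = field(repr=False)
    threshold_value: float = float("nan")


def zstack_height(stack: ZStack, cfg: MitoConfig = MitoConfig()) -> HeightResult:
    """Height of the fluorescent structure spanned by a z-stack.

    A global threshold is applied per slice and a slice has signal when its
    foreground area exceeds ``min_slice_area_um2``; height = (last signal
    slice - first signal slice + 1) x z_step.  The default threshold is the
    stack median plus ``threshold_nsigma`` robust SDs (puncta fill far too
    little of a slice for a histogram split); ``threshold_method='otsu'``
    uses Otsu on the maximum projection instead.
    """
    if cfg.threshold_method == "otsu":
        try:
            _, t = threshold(stack.max_projection(), "otsu")
        except ConstantImageError:
            warnings.warn("constant stack; height undefined, returning 0")
            return HeightResult(0.0, None, None, np.zeros(stack.n_slices))
    else:
        med = float(np.median(stack.slices))
        mad = 1.4826 * float(np.median(np.abs(stack.slices - med)))
        if mad == 0 and stack.slices.max() == med:
            warnings.warn("constant stack; height undefined, returning 0")
            return HeightResult(0.0, None, None, np.zeros(stack.n_slices))
        t = med + cfg.threshold_nsigma * max(mad, 1e-12)
    areas = (stack.slices > t).sum(axis=(1, 2)) * stack.pixel_size**2
    signal = np.flatnonzero(areas > cfg.min_slice_area_um2)
    if signal.size == 0:
        warnings.warn("no slice exceeds the signal criterion; height 0")
        return HeightResult(0.0, None, None, areas, t)
    first, last = int(signal[0]), int(signal[-1])
    return HeightResult((last - first + 1) * stack.z_step, first, last, areas, t)


@dataclass(frozen=True)
class AreaRatio:
    ratio: float
    area_a_um2: float
    area_b_um2: float
    valid: bool


def area_ratio(chan_a: CalibratedImage, chan_b: CalibratedImage) -> AreaRatio:
    """Foreground-area ratio A/B after per-channel Otsu binarisation.

    Used for the mitochondria / total alpha-synuclein coverage ratio.  A
    channel with no foreground makes the ratio undefined (flagged, nan).
    """
    if chan_a.shape != chan_b.shape or chan_a.pixel_size != chan_b.pixel_size:
        raise ValueError("channels must share shape and calibration")
    area = []
    for chan in (chan_a, chan_b):
        try:
            mask, _ = threshold(chan, "otsu")
            area.append(float(mask.sum()) * chan.pixel_size**2)
        except ConstantImageError:
            area.append(0.0)
    area_a, area_b = area
    if area_b == 0:
        warnings.warn("denominator channel has no foreground; ratio undefined")
        return AreaRatio(float("nan"), area_a, area_b, False)
    return AreaRatio(area_a / area_b, area_a, area_b, True)
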