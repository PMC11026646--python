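"""Calibrated image containers and multi-page TIFF I/O.

Every analysis operates on luminance arrays that carry their physical
calibration with them: micrometres per pixel for single images, seconds per
frame for time-lapse series, and micrometres per slice for z-stacks.  All
physical thresholds elsewhere in the package (the 5 um^2 size cut, the 15 um
overlap cut-off, top-hat radii) are expressed in micrometres and converted
through these calibrations, so images must never be passed around as bare
arrays.

Coordinates follow the (row, col) convention, 0-based, referring to pixel
centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


class ConstantImageError(ValueError):
    """Raised when a histogram threshold is requested for a constant image."""


def _check_luminance(pixels: np.ndarray, ndim: int, name: str) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-D, got shape {pixels.shape}")
    if not np.all(np.isfinite(pixels)):
        raise ValueError(f"{name} contains non-finite luminance values")
    if pixels.min() < 0:
        raise ValueError(f"{name} contains negative luminance values")
    return pixels


@dataclass(frozen=True)
class CalibratedImage:
    """A single-channel luminance image with physical pixel size.

    Parameters
    ----------
    pixels:
        2-D array of non-negative, finite luminance values.
    pixel_size:
        Lateral calibration in micrometres per pixel (isotropic).
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _check_luminance(self.pixels, 2, "image"))
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def um2_per_px(self) -> float:
        return self.pixel_size**2

    def crop(self, row_start: int, row_stop: int, col_start: int, col_stop: int) -> "CalibratedImage":
        return CalibratedImage(self.pixels[row_start:row_stop, col_start:col_stop], self.pixel_size)


@dataclass(frozen=True)
class ImageSeries:
    """A time-lapse of same-shape calibrated frames at a uniform interval."""

    frames: np.ndarray  # (T, H, W)
    pixel_size: float
    frame_interval: float  # seconds between consecutive frames

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", _check_luminance(self.frames, 3, "series"))
        if self.frames.shape[0] < 1:
            raise ValueError("series needs at least one frame")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Span from the first to one interval past the last frame, seconds."""
        return self.n_frames * self.frame_interval

    def frame(self, t: int) -> CalibratedImage:
        return CalibratedImage(self.frames[t], self.pixel_size)


@dataclass(frozen=True)
class ZStack:
    """An axial stack of calibrated slices with a known z step."""

    slices: np.ndarray  # (Z, H, W)
    pixel_size: float
    z_step: float  # micrometres between consecutive slices

    def __post_init__(self) -> None:
        object.__setattr__(self, "slices", _check_luminance(self.slices, 3, "stack"))
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.z_step > 0:
            raise ValueError("z_step must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def max_projection(self) -> CalibratedImage:
        return CalibratedImage(self.slices.max(axis=0), self.pixel_size)


# ---------------------------------------------------------------------------
# TIFF I/O.  Images are written as 16-bit grayscale multi-page TIFF with the
# pixel size in the resolution tags and the temporal/axial calibration in
# ImageJ-style metadata, which is what Fiji and most viewers expect.
# ---------------------------------------------------------------------------

def _quantize(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)


def _imagej_kwargs(pixel_size: float, **meta: float) -> dict:
    return {
        "imagej": True,
        "resolution": (1.0 / pixel_size, 1.0 / pixel_size),
        "metadata": {"unit": "um", **meta},
    }


def write_image(path, image: CalibratedImage) -> None:
    tifffile.imwrite(path, _quantize(image.pixels), **_imagej_kwargs(image.pixel_size))


def write_series(path, series: ImageSeries) -> None:
    tifffile.imwrite(
        path,
        _quantize(series.frames),
        **_imagej_kwargs(series.pixel_size, finterval=series.frame_interval),
    )


def write_stack(path, stack: ZStack) -> None:
    tifffile.imwrite(
        path,
        _quantize(stack.slices),
        **_imagej_kwargs(stack.pixel_size, spacing=stack.z_step),
    )


def _read_calibration(tif: tifffile.TiffFile) -> tuple[float, dict]:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    pixel_size = None
    if tag is not None:
        num, den = tag.value
        if num:
            pixel_size = den / num
    meta = tif.imagej_metadata or {}
    return pixel_size, meta


def read_image(path, pixel_size: float | None = None) -> CalibratedImage:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        ps, _ = _read_calibration(tif)
    ps = pixel_size if pixel_size is not None else ps
    if ps is None:
        raise ValueError(f"{path}: no pixel-size calibration in file; pass pixel_size")
    if data.ndim == 3:  # single-page file read back as (1, H, W)
        data = data[0]
    return CalibratedImage(data, ps)


def read_series(path, pixel_size: float | None = None, frame_interval: float | None = None) -> ImageSeries:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        ps, meta = _read_calibration(tif)
    ps = pixel_size if pixel_size is not None else ps
    dt = frame_interval if frame_interval is not None else meta.get("finterval")
    if ps is None or dt is None:
        raise ValueError(f"{path}: missing calibration; pass pixel_size/frame_interval")
    if data.ndim == 2:
        data = data[None]
    return ImageSeries(data, ps, dt)


def read_stack(path, pixel_size: float | None = None, z_step: float | None = None) -> ZStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        ps, meta = _read_calibration(tif)
    ps = pixel_size if pixel_size is not None else ps
    dz = z_step if z_step is not None else meta.get("spacing")
    if ps is None or dz is None:
        raise ValueError(f"{path}: missing calibration; pass pixel_size/z_step")
    if data.ndim == 2:
        data = data[None]
    return ZStack(data, ps, dz)
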