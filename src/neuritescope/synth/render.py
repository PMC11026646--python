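"""Low-level rendering helpers for synthetic fluorescence scenes.

Objects are diffraction-limited puncta drawn as isotropic Gaussian blobs
(sigma = PSF sigma); calibration objects are sharp-edged discs with an exact,
countable pixel footprint.  Backgrounds combine a flat level with a linear
ramp across columns — the nonuniform illumination the top-hat stage is there
to remove.
"""

from __future__ import annotations

import numpy as np


def stamp_gaussian(img: np.ndarray, row: float, col: float, sigma: float, amplitude: float) -> None:
    """Add an isotropic Gaussian blob (in place), truncated at 5 sigma."""
    h, w = img.shape
    half = int(np.ceil(5 * sigma))
    r0, r1 = max(0, int(np.floor(row)) - half), min(h, int(np.floor(row)) + half + 1)
    c0, c1 = max(0, int(np.floor(col)) - half), min(w, int(np.floor(col)) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    img[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def stamp_gaussian_max(img: np.ndarray, row: float, col: float, sigma: float, amplitude: float) -> None:
    """Compose a Gaussian blob by maximum, for constant-intensity curves."""
    h, w = img.shape
    half = int(np.ceil(5 * sigma))
    r0, r1 = max(0, int(np.floor(row)) - half), min(h, int(np.floor(row)) + half + 1)
    c0, c1 = max(0, int(np.floor(col)) - half), min(w, int(np.floor(col)) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    blob = amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))
    np.maximum(img[r0:r1, c0:c1], blob, out=img[r0:r1, c0:c1])


def stamp_disc(img: np.ndarray, row: int, col: int, radius_px: float, amplitude: float) -> int:
    """Add a sharp-edged disc; returns its exact pixel count."""
    h, w = img.shape
    half = int(np.ceil(radius_px)) + 1
    r0, r1 = max(0, row - half), min(h, row + half + 1)
    c0, c1 = max(0, col - half), min(w, col + half + 1)
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    inside = rr**2 + cc**2 <= radius_px**2
    img[r0:r1, c0:c1] += amplitude * inside
    return int(inside.sum())


def disc_pixel_count(radius_px: float) -> int:
    half = int(np.ceil(radius_px)) + 1
    rr = np.arange(-half, half + 1)[:, None]
    cc = np.arange(-half, half + 1)[None, :]
    return int((rr**2 + cc**2 <= radius_px**2).sum())


def disc_radius_for_area(area_um2: float, pixel_size: float) -> float:
    """Radius (px) whose rasterised disc has pixel area closest to area_um2."""
    target_px = area_um2 / pixel_size**2
    r = np.sqrt(target_px / np.pi)
    best_r, best_err = r, abs(disc_pixel_count(r) - target_px)
    for dr in np.linspace(-1.0, 1.0, 81):
        cand = r + dr
        if cand <= 0.5:
            continue
        err = abs(disc_pixel_count(cand) - target_px)
        if err < best_err:
            best_r, best_err = cand, err
    return best_r


def background_field(shape: tuple[int, int], level: float, ramp: float) -> np.ndarray:
    """Flat level plus a linear left-to-right illumination ramp."""
    h, w = shape
    cols = np.linspace(0.0, 1.0, w)[None, :]
    return level + ramp * np.broadcast_to(cols, (h, w)).copy()


def add_noise(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise, clipped at zero (luminance is non-negative)."""
    if sigma <= 0:
        return np.clip(img, 0, None)
    return np.clip(img + rng.normal(0.0, sigma, img.shape), 0, None)


def gaussian_fwhm_area_px(sigma: float) -> float:
    """Half-maximum footprint of a Gaussian blob, pixels (2 pi sigma^2 ln 2)."""
    return 2.0 * np.pi * sigma**2 * np.log(2.0)
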