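"""Synthetic fluorescence scenes with ground truth.

Four generators cover the imaging assays:

* ``gen_mito_series`` — time-lapse of tunnel segments containing stationary
  and motile diffraction-limited puncta (mitochondria), plus optional
  sharp-edged calibration discs of exact known area for testing the size
  rejection rule.
* ``gen_neurite_image`` — curvilinear neurites whose free termini carry
  brighter boutons; the generating path graph defines the true terminus
  count.
* ``gen_synapse_channels`` — two puncta channels with a stated subset of
  co-located footprints of known overlap size.
* ``gen_zstack`` — a punctum field confined to a known contiguous slice
  range, for the height measure.

All randomness derives from ``SimParams.seed`` through named sub-streams, so
identical parameters give bit-identical scenes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from ..images import CalibratedImage, ImageSeries, ZStack
from .params import SimParams
from .render import (
    add_noise,
    background_field,
    disc_radius_for_area,
    gaussian_fwhm_area_px,
    stamp_disc,
    stamp_gaussian,
    stamp_gaussian_max,
)
from .truth import GroundTruth

_MITO_COLUMNS = (
    "kind", "tunnel", "motile", "x_px", "y_px", "x_um", "speed_um_s",
    "sigma_px", "amplitude", "area_um2",
)


def _sample_min_sep(
    rng: np.random.Generator,
    n: int,
    lo: float,
    hi: float,
    min_sep: float,
    avoid: list[tuple[float, float]] | None = None,
    max_tries: int = 50_000,
) -> np.ndarray:
    """Draw n values in [lo, hi] pairwise separated by min_sep.

    ``avoid`` is a list of (centre, clearance) exclusion intervals.
    """
    avoid = avoid or []
    xs: list[float] = []
    for _ in range(max_tries):
        if len(xs) == n:
            break
        x = rng.uniform(lo, hi)
        if any(abs(x - q) < min_sep for q in xs):
            continue
        if any(abs(x - c) < cl for c, cl in avoid):
            continue
        xs.append(x)
    if len(xs) < n:
        raise ValueError(
            f"could not place {n} objects in [{lo:.0f}, {hi:.0f}] at separation {min_sep}"
        )
    return np.array(xs)


def _grid_positions(
    rng: np.random.Generator,
    n: int,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    min_sep: float,
    avoid: list[tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Jittered-grid placement guaranteeing pairwise separation >= min_sep."""
    jitter = 1.5
    cell = min_sep + 2 * jitter
    gx = np.arange(x_range[0] + cell / 2, x_range[1] - cell / 2 + 1e-9, cell)
    gy = np.arange(y_range[0] + cell / 2, y_range[1] - cell / 2 + 1e-9, cell)
    if gx.size == 0 or gy.size == 0:
        raise ValueError("tunnel too small for grid placement")
    sites = np.array([(y, x) for y in gy for x in gx])
    if avoid:
        keep = np.ones(len(sites), dtype=bool)
        for (cy, cx, clearance) in avoid:
            d2 = (sites[:, 0] - cy) ** 2 + (sites[:, 1] - cx) ** 2
            keep &= d2 >= clearance**2
        sites = sites[keep]
    if len(sites) < n:
        raise ValueError(f"only {len(sites)} grid sites for {n} objects")
    pick = rng.choice(len(sites), size=n, replace=False)
    return sites[pick] + rng.uniform(-jitter, jitter, size=(n, 2))


def gen_mito_series(params: SimParams) -> tuple[ImageSeries, GroundTruth]:
    """Render a tunnel time-lapse; returns the series and its ground truth.

    Stationary puncta sit at fixed positions; motile ones advance along the
    tunnel axis by speed x frame_interval per frame (positive speed =
    anterograde = increasing column).  Placement rejects parameter sets whose
    objects cannot stay inside the tunnel for the whole series.
    """
    shape = params.frame_shape
    rois = params.tunnel_rois()
    sigma = params.psf_sigma_px
    ps = params.pixel_size
    static = background_field(shape, params.background, params.background_ramp)
    records: list[dict] = []
    motile_objs: list[tuple[float, float, float]] = []  # (row, col0, px_per_frame)

    for i, roi in enumerate(rois):
        rng = params.rng_for("mito", i)
        L, w = roi.length_px, roi.width_px
        pad = 6.0
        y_lo, y_hi = 2.0, max(w - 3.0, 2.5)

        # calibration discs first: they need the most clearance
        patch_centers: list[tuple[float, float]] = []
        for area in params.injected_patch_areas_um2:
            r = disc_radius_for_area(area, ps)
            if 2 * r > w - 4:
                raise ValueError(f"patch of {area} um^2 does not fit tunnel width {w} px")
            avoid = [(c, r + 25.0) for c, _ in patch_centers]
            x = _sample_min_sep(rng, 1, pad + r, L - pad - r, 1.0, avoid=avoid)[0]
            y = w / 2.0
            count = stamp_disc(
                static, roi.row_start + int(round(y)), roi.col_start + int(round(x)),
                r, 2.0 * params.amplitude,
            )
            patch_centers.append((x, r))
            records.append(dict(
                kind="patch", tunnel=roi.tunnel_id, motile=False,
                x_px=roi.col_start + round(x), y_px=roi.row_start + round(y),
                x_um=x * ps, speed_um_s=0.0, sigma_px=np.nan,
                amplitude=2.0 * params.amplitude, area_um2=count * ps**2,
            ))

        patch_avoid = [(c, r + params.min_separation_px) for c, r in patch_centers]

        # stationary puncta
        if params.n_stationary > 0:
            if params.placement == "grid":
                avoid_2d = [(w / 2.0, c, r + params.min_separation_px) for c, r in patch_centers]
                pos = _grid_positions(
                    rng, params.n_stationary, (pad, L - pad), (y_lo, y_hi),
                    params.min_separation_px, avoid=avoid_2d,
                )
                ys_s, xs_s = pos[:, 0], pos[:, 1]
            else:
                xs_s = _sample_min_sep(
                    rng, params.n_stationary, pad, L - pad,
                    params.min_separation_px, avoid=patch_avoid,
                )
                ys_s = rng.uniform(y_lo, y_hi, params.n_stationary)
            for x, y in zip(xs_s, ys_s):
                stamp_gaussian(static, roi.row_start + y, roi.col_start + x, sigma, params.amplitude)
                fwhm_px = gaussian_fwhm_area_px(sigma)
                records.append(dict(
                    kind="mito", tunnel=roi.tunnel_id, motile=False,
                    x_px=roi.col_start + x, y_px=roi.row_start + y,
                    x_um=x * ps, speed_um_s=0.0, sigma_px=sigma,
                    amplitude=params.amplitude, area_um2=fwhm_px * ps**2,
                ))

        # motile puncta
        if params.n_motile > 0:
            if params.speeds is not None:
                speeds = [params.speeds[k % len(params.speeds)] for k in range(params.n_motile)]
            else:
                mags = rng.uniform(*params.speed_range, params.n_motile)
                signs = np.where(rng.random(params.n_motile) < params.anterograde_prob, 1.0, -1.0)
                speeds = list(mags * signs)
            x0s: list[float] = []
            for v in speeds:
                v_px = v * params.frame_interval / ps  # px per frame, signed
                disp = v_px * (params.n_frames - 1)
                lo = pad + max(0.0, -disp)
                hi = L - pad - max(0.0, disp)
                if hi <= lo:
                    raise ValueError(
                        f"speed {v} um/s cannot stay inside a {params.tunnel_length_um} um "
                        f"tunnel for {params.n_frames} frames"
                    )
                x0 = _sample_min_sep(
                    rng, 1, lo, hi, params.min_separation_px,
                    avoid=[(q, params.min_separation_px) for q in x0s] + patch_avoid,
                )[0]
                x0s.append(x0)
                y = rng.uniform(y_lo, y_hi)
                motile_objs.append((roi.row_start + y, roi.col_start + x0, v_px))
                fwhm_px = gaussian_fwhm_area_px(sigma)
                records.append(dict(
                    kind="mito", tunnel=roi.tunnel_id, motile=True,
                    x_px=roi.col_start + x0, y_px=roi.row_start + y,
                    x_um=x0 * ps, speed_um_s=v, sigma_px=sigma,
                    amplitude=params.amplitude, area_um2=fwhm_px * ps**2,
                ))

    frames = np.empty((params.n_frames,) + shape, dtype=np.float64)
    for t in range(params.n_frames):
        frame = static.copy()
        for (row, col0, v_px) in motile_objs:
            stamp_gaussian(frame, row, col0 + v_px * t, sigma, params.amplitude)
        frames[t] = add_noise(frame, params.noise_sigma, params.rng_for("mito-noise", t))

    truth = GroundTruth(
        pd.DataFrame(records, columns=list(_MITO_COLUMNS)),
        meta={
            "scene": "mito_series",
            "pixel_size": ps,
            "frame_interval": params.frame_interval,
            "rois": [r.__dict__ for r in rois],
        },
    )
    return ImageSeries(frames, ps, params.frame_interval), truth


# ---------------------------------------------------------------------------


def _smooth_path(rng, x0, x1, y_center, y_amp, n_ctrl=6, step=0.5):
    cx = np.linspace(x0, x1, n_ctrl)
    cy = y_center + rng.uniform(-y_amp, y_amp, n_ctrl)
    spline = CubicSpline(cx, cy)
    xs = np.arange(x0, x1 + step / 2, step)
    return xs, spline(xs)


def gen_neurite_image(params: SimParams) -> tuple[CalibratedImage, GroundTruth]:
    """Render curvilinear neurites with boutons at every free terminus.

    Each neurite occupies its own horizontal band, runs monotonically in x,
    and may carry side branches (monotone in y) whose tips are additional
    termini, so the true terminus count is 2 x n_neurites + n_branches.
    """
    h, w = params.image_shape
    n = params.n_neurites
    n_termini = params.n_termini if params.n_termini is not None else 2 * max(n, 0)
    if n == 0:
        if n_termini:
            raise ValueError("termini requested without neurites")
        img = add_noise(
            background_field((h, w), params.background, params.background_ramp),
            params.amplitude / params.neurite_snr, params.rng_for("neurite-noise"),
        )
        truth = GroundTruth(pd.DataFrame({"kind": [], "x_px": [], "y_px": [], "neurite": []}),
                            meta={"scene": "neurites", "n_termini": 0,
                                  "neurite_mask_area_um2": 0.0, "pixel_size": params.pixel_size})
        return CalibratedImage(img, params.pixel_size), truth

    n_extra = n_termini - 2 * n
    if n_extra < 0:
        raise ValueError("n_termini must be at least 2 per neurite")
    if n_extra > 4 * n:
        raise ValueError("at most 4 branches per neurite supported")
    branches_per = [n_extra // n + (1 if k < n_extra % n else 0) for k in range(n)]

    sigma = params.psf_sigma_px
    amp = params.amplitude
    margin = 25
    band_h = h // n
    clean = np.zeros((h, w))
    records: list[dict] = []

    for k in range(n):
        rng = params.rng_for("neurite", k)
        band_lo = k * band_h + 8
        band_hi = (k + 1) * band_h - 8
        center = 0.5 * (band_lo + band_hi)
        y_amp = 0.18 * (band_hi - band_lo)
        xs, ys = _smooth_path(rng, margin, w - margin, center, y_amp)
        for x, y in zip(xs, ys):
            stamp_gaussian_max(clean, y, x, sigma, amp)
        termini = [(ys[0], xs[0]), (ys[-1], xs[-1])]

        slots = [0.25, 0.4, 0.55, 0.7]
        for b in range(branches_per[k]):
            u = slots[b] + rng.uniform(-0.03, 0.03)
            j = int(u * (len(xs) - 1))
            bx0, by0 = xs[j], ys[j]
            direction = 1 if b % 2 == 0 else -1
            y_end = band_hi - 4 if direction > 0 else band_lo + 4
            length = abs(y_end - by0)
            if length < 12:
                y_end = by0 + direction * 12
            by = np.arange(by0, y_end, direction * 0.5)
            wiggle = np.cumsum(rng.uniform(-0.15, 0.15, by.size))
            bxs = bx0 + np.linspace(0, rng.uniform(-8, 8), by.size) + wiggle
            for x, y in zip(bxs, by):
                stamp_gaussian_max(clean, y, x, sigma, amp)
            termini.append((by[-1], bxs[-1]))

        for (ty, tx) in termini:
            stamp_gaussian_max(clean, ty, tx, 1.5 * sigma, params.bouton_gain * amp)
            records.append(dict(kind="bouton", x_px=tx, y_px=ty, neurite=k))
        records.append(dict(kind="neurite", x_px=np.nan, y_px=np.nan, neurite=k))

    truth_mask_area = float((clean >= 0.5 * amp).sum()) * params.pixel_size**2
    img = add_noise(
        clean + background_field((h, w), params.background, params.background_ramp),
        amp / params.neurite_snr, params.rng_for("neurite-noise"),
    )
    truth = GroundTruth(
        pd.DataFrame(records),
        meta={"scene": "neurites", "n_termini": int(n_termini),
              "neurite_mask_area_um2": truth_mask_area, "pixel_size": params.pixel_size},
    )
    return CalibratedImage(img, params.pixel_size), truth


# ---------------------------------------------------------------------------


def gen_synapse_channels(params: SimParams) -> tuple[CalibratedImage, CalibratedImage, GroundTruth]:
    """Two-channel puncta field with a stated subset of co-located footprints.

    Overlapping objects are sharp-edged discs stamped at the same centre in
    both channels, so the true overlap footprint is an exact pixel set; the
    truth records its equivalent diameter and whether it exceeds the 15 um
    reporting cut-off.  Unpaired puncta keep a clearance from everything so
    the channel masks are disjoint away from the stated overlaps.
    """
    h, w = params.image_shape
    ps = params.pixel_size
    rng = params.rng_for("synapse")
    amp = params.amplitude
    chan_a = background_field((h, w), params.background, params.background_ramp)
    chan_b = background_field((h, w), params.background, 0.6 * params.background_ramp)
    records: list[dict] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)

    def place(radius_px: float, margin: float = 6.0) -> tuple[int, int]:
        for _ in range(20_000):
            y = rng.uniform(radius_px + 4, h - radius_px - 4)
            x = rng.uniform(radius_px + 4, w - radius_px - 4)
            if all(np.hypot(y - py, x - px) >= radius_px + pr + margin for py, px, pr in placed):
                placed.append((y, x, radius_px))
                return int(round(y)), int(round(x))
        raise ValueError("could not place synapse objects without contact")

    for d_um in params.overlap_diameters_um:
        r = d_um / 2.0 / ps
        y, x = place(r)
        count = stamp_disc(chan_a, y, x, r, amp)
        stamp_disc(chan_b, y, x, r, amp)
        eq_diam = 2.0 * np.sqrt(count / np.pi) * ps
        records.append(dict(
            kind="overlap", channel="AB", x_px=x, y_px=y,
            area_um2=count * ps**2, eq_diam_um=eq_diam,
            exceeds_cutoff=bool(eq_diam > 15.0),
        ))

    r_punct = params.punctum_diameter_um / 2.0 / ps
    for channel, img in (("A", chan_a), ("B", chan_b)):
        for _ in range(params.n_puncta):
            y, x = place(r_punct)
            count = stamp_disc(img, y, x, r_punct, amp)
            records.append(dict(
                kind="punctum", channel=channel, x_px=x, y_px=y,
                area_um2=count * ps**2,
                eq_diam_um=2.0 * np.sqrt(count / np.pi) * ps,
                exceeds_cutoff=False,
            ))

    noise = params.amplitude / params.neurite_snr
    chan_a = add_noise(chan_a, noise, params.rng_for("synapse-noise", "A"))
    chan_b = add_noise(chan_b, noise, params.rng_for("synapse-noise", "B"))
    cols = ["kind", "channel", "x_px", "y_px", "area_um2", "eq_diam_um", "exceeds_cutoff"]
    truth = GroundTruth(
        pd.DataFrame(records, columns=cols),
        meta={"scene": "synapses", "pixel_size": ps,
              "n_overlaps": len(params.overlap_diameters_um)},
    )
    return CalibratedImage(chan_a, ps), CalibratedImage(chan_b, ps), truth


# ---------------------------------------------------------------------------


def gen_zstack(params: SimParams) -> tuple[ZStack, GroundTruth]:
    """Z-stack whose signal is confined to a known contiguous slice range."""
    z0, z1 = params.signal_slices
    if not (0 <= z0 <= z1 < params.n_slices):
        raise ValueError(
            f"signal slices {params.signal_slices} must lie inside the {params.n_slices}-slice stack"
        )
    h, w = params.stack_shape
    rng = params.rng_for("zstack")
    pattern = np.zeros((h, w))
    records = []
    for _ in range(params.n_stack_puncta):
        y = rng.uniform(6, h - 6)
        x = rng.uniform(6, w - 6)
        stamp_gaussian(pattern, y, x, params.psf_sigma_px, params.amplitude)
        records.append(dict(kind="stack_punctum", x_px=x, y_px=y))
    bg = background_field((h, w), params.background, params.background_ramp)
    slices = np.empty((params.n_slices, h, w))
    for z in range(params.n_slices):
        img = bg + (pattern if z0 <= z <= z1 else 0.0)
        slices[z] = add_noise(img, params.noise_sigma, params.rng_for("zstack-noise", z))
    height = (z1 - z0 + 1) * params.z_step
    truth = GroundTruth(
        pd.DataFrame(records, columns=["kind", "x_px", "y_px"]),
        meta={"scene": "zstack", "height_um": height, "first_slice": z0,
              "last_slice": z1, "z_step": params.z_step},
    )
    return ZStack(slices, params.pixel_size, params.z_step), truth
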