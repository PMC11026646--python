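"""Kymograph construction and mitochondrial motility analysis.

A kymograph collapses a tunnel time-lapse to a time x distance matrix: each
row is the mean luminance across the tunnel width at every position along
the axis, rows stacked in time order.  Stationary mitochondria appear as
vertical stripes and are suppressed by subtracting the per-column temporal
median (robust to a motile object transiting the column); motile
mitochondria appear as slanted lines, detected by binarising the filtered
kymograph, skeletonising, splitting the skeleton at junctions and fitting a
line per branch.  Speed is |slope| x column size / row interval — the change
in distance along the tunnel divided by the change in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import morphology

from .images import CalibratedImage, ConstantImageError, ImageSeries
from .primitives import threshold
from .roi import TunnelROI


@dataclass(frozen=True)
class Kymograph:
    matrix: np.ndarray          # rows = time, cols = distance along tunnel
    row_interval: float         # s per row
    col_size: float             # um per column
    tunnel_id: str = "tunnel"
    anterograde_sign: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D")
        object.__setattr__(self, "matrix", m)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class Track:
    """One fitted kymograph trajectory."""

    rows: np.ndarray = field(repr=False)      # skeleton pixel rows (time)
    cols: np.ndarray = field(repr=False)      # skeleton pixel cols (distance)
    slope_px_per_row: float
    intercept_px: float
    r_squared: float
    speed_um_s: float
    net_displacement_um: float
    path_length_um: float
    direction: str                            # anterograde|retrograde|bidirectional|stationary

    @property
    def n_rows_spanned(self) -> int:
        return int(self.rows.max() - self.rows.min() + 1)


@dataclass(frozen=True)
class KymoConfig:
    threshold_method: str = "robust"  # 'robust' (median + n*MAD) or 'otsu'
    threshold_nsigma: float = 4.0
    smooth_sigma_px: float = 1.2   # row-wise matched filter (PSF-sized)
    denoise_min_px: int = 4        # drop isolated supra-threshold noise first
    close_shape_px: tuple[int, int] = (5, 13)  # (rows, cols) closing footprint
    min_track_px: int = 20         # minimum mask support per track
    min_branch_rows: int = 10      # minimum time extent, rows
    min_r2: float = 0.8
    min_disp_um: float = 2.0       # below this net displacement: not motile
    min_path_um: float = 6.0       # fluctuating path length for 'bidirectional'
    stripe_nsigma: float = 5.0     # stripe peak height over the profile noise
    seed_min_rows: int = 4         # shortest fragment allowed to seed a line
    assembly_tol_px: float = 5.0   # fragment-to-line distance for assembly
    min_line_occupancy: float = 0.6  # fraction of rows with signal on the line


@dataclass(frozen=True)
class StationaryFilterResult:
    kymograph: Kymograph
    n_stationary: int
    stripe_cols: np.ndarray


def build_kymograph(series: ImageSeries, roi: TunnelROI) -> Kymograph:
    """Average across the tunnel width, stacking frames as rows."""
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to build a kymograph")
    sub = roi.extract(series.frames)          # (T, width, length); validates bounds
    matrix = sub.mean(axis=1)
    return Kymograph(matrix, series.frame_interval, series.pixel_size,
                     roi.tunnel_id, roi.anterograde_sign)


def suppress_stationary(kymo: Kymograph, cfg: KymoConfig = KymoConfig()) -> StationaryFilterResult:
    """Remove vertical stripes and count the stationary mitochondria.

    The per-column temporal median is subtracted (clipped at zero); the
    stationary count is the number of peaks in the median profile that rise
    ``stripe_nsigma`` robust SDs above its baseline — one peak per resolved
    stationary object, adjacent columns of one stripe merging into one peak.
    """
    if kymo.n_rows < 3:
        raise ValueError("need at least 3 rows to estimate the stationary profile")
    med = np.median(kymo.matrix, axis=0)
    filtered = np.clip(kymo.matrix - med[None, :], 0.0, None)
    baseline = np.median(med)
    # noise scale from the lower quartile: the stripes themselves inflate
    # the upper side of the profile distribution
    noise = (baseline - np.percentile(med, 25)) / 0.6745
    height = baseline + cfg.stripe_nsigma * noise
    prominence = max(cfg.stripe_nsigma * noise, 1e-12)
    peaks, _ = find_peaks(med, height=height if noise > 0 else None,
                          prominence=prominence)
    out = Kymograph(filtered, kymo.row_interval, kymo.col_size,
                    kymo.tunnel_id, kymo.anterograde_sign)
    return StationaryFilterResult(out, int(peaks.size), peaks)


def _fit_branch(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through per-row mean columns; returns slope, icpt, R^2."""
    rows_u, inv = np.unique(rows, return_inverse=True)
    col_mean = np.bincount(inv, weights=cols.astype(float)) / np.bincount(inv)
    slope, icpt = np.polyfit(rows_u, col_mean, 1)
    pred = slope * rows_u + icpt
    ss_res = float(np.sum((col_mean - pred) ** 2))
    ss_tot = float(np.sum((col_mean - col_mean.mean()) ** 2))
    if ss_tot < 1e-9:
        r2 = 1.0 if ss_res < 0.5 * rows_u.size else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(icpt), r2


def _line_occupancy(matrix: np.ndarray, thr: float, slope: float, icpt: float,
                    r0: int, r1: int) -> float:
    """Fraction of rows in [r0, r1] with supra-threshold signal on the line."""
    h, w = matrix.shape
    rows = np.arange(max(r0, 0), min(r1, h - 1) + 1)
    cols = np.rint(slope * rows + icpt).astype(int)
    hits = 0
    for r, c in zip(rows, cols):
        c0, c1 = max(c - 2, 0), min(c + 3, w)
        if c1 > c0 and matrix[r, c0:c1].max() > thr:
            hits += 1
    return hits / max(rows.size, 1)


def _row_gap(rows_a: np.ndarray, rows_b: np.ndarray) -> int:
    """Smallest time separation between two pixel sets (0 if they overlap)."""
    a0, a1 = int(rows_a.min()), int(rows_a.max())
    b0, b1 = int(rows_b.min()), int(rows_b.max())
    if b0 > a1:
        return b0 - a1
    if a0 > b1:
        return a0 - b1
    return 0


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), np.uint8))
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[labels]


def detect_tracks(filtered: Kymograph, cfg: KymoConfig = KymoConfig()) -> list[Track]:
    """Detect slanted-line trajectories in a stationary-suppressed kymograph.

    Rows are first convolved with a PSF-sized Gaussian (a matched filter
    along the distance axis, which cannot smear the slope), then binarised.
    The default threshold is noise-referenced — the matrix median plus
    ``threshold_nsigma`` robust SDs — because the foreground of a filtered
    kymograph occupies far too small a histogram fraction for Otsu to
    separate it from noise; ``threshold_method='otsu'`` restores the
    histogram split for high-contrast data.  The skeleton is split at
    junctions, and fragments are assembled into tracks by a seeded line
    fit: the longest fragment seeds a line, nearby fragments lying on it
    are absorbed (refitting as the group grows), which repairs tracks
    interrupted by noise drop-outs and residual stripe crossings without
    trusting the slope of any short fragment on its own.
    """
    matrix = np.clip(filtered.matrix, 0, None)
    if cfg.smooth_sigma_px > 0:
        matrix = ndimage.gaussian_filter1d(matrix, cfg.smooth_sigma_px, axis=1)
    if cfg.threshold_method == "otsu":
        try:
            mask, thr = threshold(CalibratedImage(matrix, filtered.col_size), "otsu")
        except ConstantImageError:
            return []
    elif cfg.threshold_method == "robust":
        med = np.median(matrix)
        sigma = 1.4826 * np.median(np.abs(matrix - med))
        if sigma == 0 and matrix.max() == med:
            return []
        thr = med + cfg.threshold_nsigma * max(sigma, 1e-12)
        mask = matrix > thr
    else:
        raise ValueError(f"unknown threshold_method {cfg.threshold_method!r}")
    mask = _drop_small(mask, cfg.denoise_min_px)
    if max(cfg.close_shape_px) > 1:
        # wide/short footprint: a fast object advances by up to ~10 px per
        # frame, so its streak is dashed along the distance axis; the
        # closing must bridge those gaps without merging rows vertically
        mask = morphology.closing(mask, np.ones(cfg.close_shape_px, bool))
    if not mask.any():
        return []
    skel = morphology.skeletonize(mask)
    neighbours = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8),
                                  mode="constant") - skel
    junctions = skel & (neighbours >= 3)
    branches, n_branches = ndimage.label(skel & ~junctions,
                                         structure=np.ones((3, 3), np.uint8))
    frags: list[dict] = []
    for lbl in range(1, n_branches + 1):
        rows, cols = np.nonzero(branches == lbl)
        frags.append(dict(rows=rows, cols=cols,
                          span=int(rows.max() - rows.min() + 1)))

    # Per-fragment anchors used for all line-residual tests: the mean
    # column at the first row, the centroid, and the mean column at the
    # last row.  Testing all three keeps misaligned long fragments out
    # while staying O(1) per fragment.
    nf = len(frags)
    anchor_r = np.zeros((3, nf))
    anchor_c = np.zeros((3, nf))
    f_npx = np.zeros(nf, dtype=int)
    f_r0 = np.zeros(nf, dtype=int)
    f_r1 = np.zeros(nf, dtype=int)
    for i, f in enumerate(frags):
        rows, cols = f["rows"], f["cols"]
        r0, r1 = rows.min(), rows.max()
        f_r0[i], f_r1[i], f_npx[i] = r0, r1, rows.size
        anchor_r[:, i] = (r0, rows.mean(), r1)
        anchor_c[:, i] = (cols[rows == r0].mean(), cols.mean(), cols[rows == r1].mean())

    def _line_resid(slope: float, icpt: float) -> np.ndarray:
        return np.abs(anchor_c - (slope * anchor_r + icpt)).max(axis=0)

    def _line_of(members: list[int]) -> tuple[float, float]:
        rows = np.concatenate([frags[i]["rows"] for i in members])
        cols = np.concatenate([frags[i]["cols"] for i in members])
        slope, icpt, _ = _fit_branch(rows, cols)
        return slope, icpt

    unassigned = set(range(nf))
    groups: list[list[int]] = []
    for seed in sorted(range(nf), key=lambda i: -frags[i]["span"]):
        if seed not in unassigned or frags[seed]["span"] < cfg.seed_min_rows:
            continue
        unassigned.remove(seed)
        group = [seed]
        g_r0, g_r1 = f_r0[seed], f_r1[seed]
        while True:
            slope, icpt = _line_of(group)
            resid = _line_resid(slope, icpt)
            best, best_dist = None, np.inf
            for f in unassigned:
                if resid[f] > cfg.assembly_tol_px:
                    continue
                dist = max(0, f_r0[f] - g_r1, g_r0 - f_r1[f])
                if dist < best_dist:
                    best, best_dist = f, dist
            if best is None:
                break
            unassigned.remove(best)
            group.append(best)
            g_r0, g_r1 = min(g_r0, f_r0[best]), max(g_r1, f_r1[best])
        groups.append(group)

    # Rescue pass for heavily dashed lines (fast objects): no fragment is
    # long enough to seed, so search lines through pairs of fragment
    # centroids and keep the best-supported inlier set, repeatedly.
    # Debris of already-found tracks must not re-assemble into ghost lines,
    # so fragments near an accepted line are removed from the pool first.
    def _strip_debris(pool: set[int], lines: list[tuple[float, float]]) -> set[int]:
        keep = np.ones(nf, dtype=bool)
        for s, c in lines:
            keep &= _line_resid(s, c) > 2 * cfg.assembly_tol_px
        return {i for i in pool if keep[i]}

    unassigned = _strip_debris(unassigned, [_line_of(g) for g in groups])
    while True:
        ids = sorted(unassigned)
        best_members: list[int] = []
        best_support = 0
        cm_r, cm_c = anchor_r[1], anchor_c[1]
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dr = cm_r[b] - cm_r[a]
                if abs(dr) < 0.6 * cfg.min_branch_rows:
                    continue
                slope = (cm_c[b] - cm_c[a]) / dr
                icpt = cm_c[a] - slope * cm_r[a]
                resid = _line_resid(slope, icpt)
                members = [i for i in ids if resid[i] <= cfg.assembly_tol_px]
                if not members:
                    continue
                span = f_r1[members].max() - f_r0[members].min() + 1
                support = int(f_npx[members].sum())
                if span >= cfg.min_branch_rows and support >= cfg.min_track_px \
                        and support > best_support:
                    best_members, best_support = members, support
        if not best_members:
            break
        groups.append(best_members)
        unassigned -= set(best_members)
        unassigned = _strip_debris(unassigned, [_line_of(best_members)])

    # leftovers long enough to stand alone (e.g. near-vertical residuals)
    for f in sorted(unassigned):
        if frags[f]["span"] >= cfg.min_branch_rows:
            groups.append([f])

    # One object can still split into two groups when both halves were long
    # enough to seed before either line stabilised; rejoin groups whose
    # fitted lines agree where they meet.
    merged = True
    while merged and len(groups) > 1:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                si, ci = _line_of(groups[i])
                sj, cj = _line_of(groups[j])
                if abs(si - sj) > 1.0:
                    continue
                rows_i = np.concatenate([frags[k]["rows"] for k in groups[i]])
                rows_j = np.concatenate([frags[k]["rows"] for k in groups[j]])
                mid = 0.5 * (rows_i.mean() + rows_j.mean())
                if abs((si * mid + ci) - (sj * mid + cj)) <= 1.5 * cfg.assembly_tol_px:
                    groups[i] = groups[i] + groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break

    tracks: list[Track] = []
    for members in groups:
        rows = np.concatenate([frags[i]["rows"] for i in members])
        cols = np.concatenate([frags[i]["cols"] for i in members])
        if rows.max() - rows.min() + 1 < cfg.min_branch_rows:
            continue
        if rows.size < cfg.min_track_px:
            continue
        slope, icpt, r2 = _fit_branch(rows, cols)
        if r2 < cfg.min_r2:
            continue
        # a real trajectory shows signal along (almost) its whole fitted
        # line; chance alignments of debris from two crossing tracks do not
        if _line_occupancy(matrix, thr, slope, icpt, int(rows.min()), int(rows.max())) \
                < cfg.min_line_occupancy:
            continue
        r0, r1 = rows.min(), rows.max()
        net_disp_um = slope * (r1 - r0) * filtered.col_size
        rows_u, inv = np.unique(rows, return_inverse=True)
        col_mean = np.bincount(inv, weights=cols.astype(float)) / np.bincount(inv)
        path_um = float(np.sum(np.abs(np.diff(col_mean)))) * filtered.col_size
        speed = abs(slope) * filtered.col_size / filtered.row_interval
        if abs(net_disp_um) < cfg.min_disp_um:
            direction = "bidirectional" if path_um >= cfg.min_path_um else "stationary"
        elif slope * filtered.anterograde_sign > 0:
            direction = "anterograde"
        else:
            direction = "retrograde"
        tracks.append(Track(rows, cols, slope, icpt, r2, speed,
                            float(net_disp_um), path_um, direction))
    return tracks


def track_speed(track: Track, kymo: Kymograph) -> float:
    """|delta columns| x column size / (delta rows x row interval), um/s."""
    return abs(track.slope_px_per_row) * kymo.col_size / kymo.row_interval


@dataclass(frozen=True)
class MotilitySummary:
    n_motile: int
    n_stationary: int
    n_anterograde: int
    n_retrograde: int
    n_bidirectional: int
    motile_ratio: float
    anterograde_fraction: float
    mean_speed_um_s: float
    valid: bool


def motility_summary(tracks: list[Track], n_stationary: int) -> MotilitySummary:
    """Motile ratio and direction balance for one tunnel.

    Motile = anterograde + retrograde tracks; fluctuating ('bidirectional')
    tracks are reported separately and excluded from the ratio, matching the
    observation that such movement is not faithfully captured by kymographs.
    """
    if n_stationary < 0:
        raise ValueError("n_stationary must be non-negative")
    motile = [t for t in tracks if t.direction in ("anterograde", "retrograde")]
    n_antero = sum(t.direction == "anterograde" for t in motile)
    n_retro = len(motile) - n_antero
    n_bidir = sum(t.direction == "bidirectional" for t in tracks)
    denom = len(motile) + n_stationary
    valid = denom > 0
    if not valid:
        warnings.warn("no mitochondria counted; motile ratio undefined")
    ratio = len(motile) / denom if valid else float("nan")
    antero_frac = n_antero / len(motile) if motile else float("nan")
    mean_speed = float(np.mean([t.speed_um_s for t in motile])) if motile else float("nan")
    return MotilitySummary(len(motile), n_stationary, n_antero, n_retro, n_bidir,
                           ratio, antero_frac, mean_speed, valid)


def analyze_series(
    series: ImageSeries,
    rois: list[TunnelROI],
    cfg: KymoConfig = KymoConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, list[Kymograph]]:
    """Full motility pipeline over every tunnel of a series.

    Returns (per-track table, per-tunnel summary table, filtered kymographs).
    """
    track_rows, summary_rows, kymos = [], [], []
    for roi in rois:
        kymo = build_kymograph(series, roi)
        filt = suppress_stationary(kymo, cfg)
        tracks = detect_tracks(filt.kymograph, cfg)
        summary = motility_summary(tracks, filt.n_stationary)
        kymos.append(filt.kymograph)
        for t in tracks:
            track_rows.append(dict(
                tunnel=roi.tunnel_id, slope_px_per_row=t.slope_px_per_row,
                speed_um_s=t.speed_um_s, direction=t.direction,
                net_displacement_um=t.net_displacement_um,
                rows_spanned=t.n_rows_spanned, r_squared=t.r_squared,
            ))
        summary_rows.append(dict(
            tunnel=roi.tunnel_id, n_motile=summary.n_motile,
            n_stationary=summary.n_stationary,
            n_bidirectional=summary.n_bidirectional,
            motile_ratio=summary.motile_ratio,
            anterograde_fraction=summary.anterograde_fraction,
            mean_speed_um_s=summary.mean_speed_um_s,
        ))
    track_cols = ["tunnel", "slope_px_per_row", "speed_um_s", "direction",
                  "net_displacement_um", "rows_spanned", "r_squared"]
    summary_cols = ["tunnel", "n_motile", "n_stationary", "n_bidirectional",
                    "motile_ratio", "anterograde_fraction", "mean_speed_um_s"]
    return (pd.DataFrame(track_rows, columns=track_cols),
            pd.DataFrame(summary_rows, columns=summary_cols), kymos)
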