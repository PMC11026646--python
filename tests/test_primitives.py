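"""Calibrated image primitives against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from neuritescope.images import CalibratedImage, ConstantImageError
from neuritescope.primitives import (
    connected_components,
    particle_analysis,
    threshold,
    tophat,
)

from conftest import make_image


# ---------------------------------------------------------------------------
# top-hat
# ---------------------------------------------------------------------------

def _opening_by_hand(img, radius):
    """Explicit erosion followed by dilation with a disc, tiny arrays only."""
    h, w = img.shape
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    offsets = [(dy, dx) for dy, dx in zip(yy.ravel(), xx.ravel())
               if dy * dy + dx * dx <= radius * radius]

    def erode(a):
        out = np.empty_like(a)
        for r in range(h):
            for c in range(w):
                vals = [a[r + dy, c + dx] for dy, dx in offsets
                        if 0 <= r + dy < h and 0 <= c + dx < w]
                out[r, c] = min(vals)
        return out

    def dilate(a):
        out = np.empty_like(a)
        for r in range(h):
            for c in range(w):
                vals = [a[r + dy, c + dx] for dy, dx in offsets
                        if 0 <= r + dy < h and 0 <= c + dx < w]
                out[r, c] = max(vals)
        return out

    return dilate(erode(img))


def test_tophat_flat_image_is_zero():
    img = make_image(np.full((16, 16), 37.0))
    assert np.allclose(tophat(img, 1.0).pixels, 0.0)


def test_tophat_matches_hand_computed_opening():
    """5x5 single bright pixel: output = input - opening, opening by hand."""
    a = np.zeros((5, 5))
    a[2, 2] = 10.0
    img = make_image(a, pixel_size=1.0)
    out = tophat(img, 2.0)
    expected = a - _opening_by_hand(a, 2)
    assert np.allclose(out.pixels, expected)


def test_tophat_removes_ramp_keeps_spot(rng):
    h, w = 40, 60
    ramp = np.linspace(0, 50, w)[None, :] * np.ones((h, 1))
    spot = np.zeros((h, w))
    spot[20, 30] = 200.0
    img = make_image(ramp + spot, pixel_size=0.5)
    out = tophat(img, 2.0).pixels
    assert out[20, 30] > 150.0
    background = out.copy()
    background[18:23, 28:33] = 0
    assert background.max() < 5.0  # ramp removed


def test_tophat_never_exceeds_input(rng):
    a = rng.uniform(0, 100, (24, 24))
    img = make_image(a)
    out = tophat(img, 1.0).pixels
    assert np.all(out <= a + 1e-9)


def test_tophat_subpixel_radius_rejected():
    img = make_image(np.zeros((8, 8)) + np.eye(8))
    with pytest.raises(ValueError, match="below one pixel"):
        tophat(img, 0.01)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def _between_class_variance(values, t):
    lo, hi = values.min(), values.max()
    hist, edges = np.histogram(values, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    below = centers <= t
    w0, w1 = hist[below].sum(), hist[~below].sum()
    if w0 == 0 or w1 == 0:
        return -1.0
    m0 = (hist[below] * centers[below]).sum() / w0
    m1 = (hist[~below] * centers[~below]).sum() / w1
    return (w0 / total) * (w1 / total) * (m0 - m1) ** 2


def _otsu_brute_force_max_variance(values):
    """Exhaustive between-class-variance maximum over all 256 bin splits."""
    lo, hi = values.min(), values.max()
    _, edges = np.histogram(values, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    return max(_between_class_variance(values, t) for t in centers[:-1])


def _triangle_brute_force(values):
    """Maximal perpendicular histogram-to-line distance (Zack's method)."""
    lo, hi = values.min(), values.max()
    hist, edges = np.histogram(values, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    peak = int(np.argmax(hist))
    nz = np.flatnonzero(hist)
    # far end: the longer tail
    if peak - nz[0] < nz[-1] - peak:
        end = nz[-1]
        ks = np.arange(peak, end + 1)
    else:
        end = nz[0]
        ks = np.arange(end, peak + 1)
    x1, y1 = peak, hist[peak]
    x2, y2 = end, hist[end]
    norm = np.hypot(x2 - x1, y2 - y1)
    dist = np.abs((y2 - y1) * ks - (x2 - x1) * hist[ks] + x2 * y1 - y2 * x1) / norm
    return centers[int(ks[np.argmax(dist)])]


def test_threshold_perfectly_separable_classes(rng):
    values = np.where(rng.random((50, 50)) < 0.9, 10.0, 200.0)
    img = make_image(values)
    for method in ("otsu", "triangle"):
        mask, t = threshold(img, method)
        assert np.array_equal(mask, values == 200.0), method


def test_otsu_matches_brute_force(rng):
    """The selected threshold attains the exhaustive-search maximum of the
    between-class variance (the variance is flat across an empty valley, so
    the threshold value itself is only determined up to that plateau)."""
    values = np.concatenate([rng.normal(60, 12, 3000), rng.normal(190, 15, 1200)])
    values = np.clip(values, 0, 255).reshape(60, 70)
    img = make_image(values)
    mask, t = threshold(img, "otsu")
    v_best = _otsu_brute_force_max_variance(values)
    assert _between_class_variance(values, t) == pytest.approx(v_best, rel=1e-9)
    # and the pixel set equals the one at the brute-force optimum
    assert np.array_equal(mask, values > t)


def test_triangle_matches_brute_force(rng):
    # skewed unimodal histogram with a bright tail, triangle's home ground
    values = np.concatenate([rng.normal(40, 8, 5000), rng.uniform(80, 250, 300)])
    values = np.clip(values, 0, 255).reshape(100, 53)
    img = make_image(values)
    _, t = threshold(img, "triangle")
    t_bf = _triangle_brute_force(values)
    bin_width = np.ptp(values) / 256
    assert abs(t - t_bf) <= 5 * bin_width


def test_threshold_affine_invariant_pixel_set(rng):
    values = np.concatenate([rng.normal(50, 10, 2000), rng.normal(180, 12, 800)])
    values = values.reshape(40, 70)
    img = make_image(values)
    mask, _ = threshold(img, "otsu")
    mask2, _ = threshold(make_image(3.0 * values + 20.0), "otsu")
    assert np.array_equal(mask, mask2)


def test_threshold_constant_image_errors():
    with pytest.raises(ConstantImageError):
        threshold(make_image(np.full((8, 8), 5.0)))


# ---------------------------------------------------------------------------
# connected components / particle analysis
# ---------------------------------------------------------------------------

def _flood_fill_labels(mask, connectivity):
    """Brute-force BFS labelling."""
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                nxt += 1
                stack = [(r, c)]
                labels[r, c] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        yy, xx = y + dy, x + dx
                        if (0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]
                                and mask[yy, xx] and labels[yy, xx] == 0):
                            labels[yy, xx] = nxt
                            stack.append((yy, xx))
    return labels


def test_components_empty_mask():
    assert connected_components(np.zeros((6, 6), bool), 0.2) == []


def test_components_diagonal_connectivity():
    mask = np.zeros((4, 4), bool)
    mask[1, 1] = mask[2, 2] = True
    assert len(connected_components(mask, 0.2, connectivity=8)) == 1
    assert len(connected_components(mask, 0.2, connectivity=4)) == 2


@pytest.mark.parametrize("connectivity", [4, 8])
def test_components_match_flood_fill(rng, connectivity):
    mask = rng.random((32, 32)) < 0.35
    comps = connected_components(mask, 0.2, connectivity)
    labels = _flood_fill_labels(mask, connectivity)
    assert len(comps) == labels.max()
    sizes_ours = sorted(c.pixel_count for c in comps)
    sizes_bf = sorted(np.bincount(labels.ravel())[1:])
    assert sizes_ours == sizes_bf


@settings(deadline=None, max_examples=25, derandomize=True)
@given(arrays(bool, (16, 16), elements=st.booleans()))
def test_components_conserve_foreground(mask):
    comps = connected_components(mask, 0.5, 8)
    assert sum(c.pixel_count for c in comps) == int(mask.sum())


def test_component_area_calibration():
    mask = np.zeros((5, 5), bool)
    mask[1:3, 1:3] = True  # 4 px
    (comp,) = connected_components(mask, 0.5, 8)
    assert comp.area_um2 == pytest.approx(4 * 0.25)
    assert comp.eccentricity == pytest.approx(0.0)  # square ~ disc-like moments


def test_particle_analysis_empty():
    stats = particle_analysis(np.zeros((5, 5), bool), 0.5)
    assert (stats.count, list(stats.sizes_um2), stats.total_area_um2) == (0, [], 0)


def test_particle_analysis_sizes():
    mask = np.zeros((10, 20), bool)
    for c0 in (0, 6, 12):
        mask[2:4, c0 : c0 + 2] = True  # three 4-px particles
    stats = particle_analysis(mask, 0.5)
    assert stats.count == 3
    assert np.allclose(stats.sizes_um2, 1.0)


def test_particle_analysis_bounds_match_component_filter(rng):
    mask = rng.random((40, 40)) < 0.3
    lo_um2, hi_um2 = 0.2, 1.0
    stats = particle_analysis(mask, 0.2, lo_um2, hi_um2)
    comps = connected_components(mask, 0.2, 8)
    expected = sorted(c.area_um2 for c in comps if lo_um2 <= c.area_um2 <= hi_um2)
    assert sorted(stats.sizes_um2) == pytest.approx(expected)
    assert stats.count == len(expected)


def test_particle_analysis_bad_bounds():
    with pytest.raises(ValueError):
        particle_analysis(np.zeros((3, 3), bool), 0.2, 2.0, 1.0)
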