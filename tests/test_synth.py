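"""Synthetic-scene generators: determinism, conservation, calibration,
and agreement with simple oracles recomputed from the rendered data."""

import numpy as np
import pytest

from neuritescope.synth import (
    SimParams,
    gen_mea_recording,
    gen_mito_series,
    gen_neurite_image,
    gen_synapse_channels,
    gen_zstack,
)


def small_params(**kw):
    defaults = dict(seed=7, n_tunnels=1, tunnel_length_um=60.0, n_frames=20,
                    n_stationary=5, n_motile=1)
    defaults.update(kw)
    return SimParams(**defaults)


# ---------------------------------------------------------------------------
# determinism / conservation / calibration
# ---------------------------------------------------------------------------

def test_identical_params_give_bit_identical_scenes():
    p = small_params()
    s1, t1 = gen_mito_series(p)
    s2, t2 = gen_mito_series(p)
    assert np.array_equal(s1.frames, s2.frames)
    assert t1.objects.equals(t2.objects)
    r1, _ = gen_mea_recording(SimParams(seed=3, n_channels=2, duration=5.0))
    r2, _ = gen_mea_recording(SimParams(seed=3, n_channels=2, duration=5.0))
    assert np.array_equal(r1.traces, r2.traces)


def test_different_seed_changes_scene():
    s1, _ = gen_mito_series(small_params(seed=1))
    s2, _ = gen_mito_series(small_params(seed=2))
    assert not np.array_equal(s1.frames, s2.frames)


def test_truth_record_conservation():
    p = small_params(n_stationary=8, n_motile=2, injected_patch_areas_um2=(4.0,),
                     tunnel_width_px=40)
    _, truth = gen_mito_series(p)
    assert len(truth.of_kind("mito")) == 10
    assert len(truth.of_kind("patch")) == 1


def test_calibration_round_trip_exact():
    """Physical truth quantities equal pixel quantities x calibration."""
    p = small_params()
    _, truth = gen_mito_series(p)
    roi_start = p.tunnel_rois()[0].col_start
    mito = truth.of_kind("mito")
    assert np.allclose(mito.x_um, (mito.x_px - roi_start) * p.pixel_size)


# ---------------------------------------------------------------------------
# mito series
# ---------------------------------------------------------------------------

def test_empty_scene_is_background_only():
    p = small_params(n_stationary=0, n_motile=0, noise_sigma=0.0)
    series, truth = gen_mito_series(p)
    assert len(truth) == 0
    # background + ramp only: every frame identical and smooth
    assert np.array_equal(series.frames[0], series.frames[-1])
    assert series.frames.max() <= p.background + p.background_ramp + 1e-9


def test_acquisition_matches_one_frame_per_second_for_a_minute():
    p = SimParams(seed=0, n_stationary=2, n_motile=0)
    series, _ = gen_mito_series(p)
    assert series.n_frames == 60
    assert series.frame_interval == 1.0
    assert series.duration == pytest.approx(60.0)


def test_motile_object_advances_five_px_per_frame():
    """1 um/s at 0.2 um/px is 5 px/frame; re-derive from the rendered argmax."""
    p = small_params(n_stationary=0, n_motile=1, speeds=(1.0,), noise_sigma=0.0,
                     background_ramp=0.0, tunnel_length_um=145.0, n_frames=20)
    series, truth = gen_mito_series(p)
    cols = [np.unravel_index(np.argmax(series.frames[t]), series.frames[t].shape)[1]
            for t in range(p.n_frames)]
    steps = np.diff(cols)
    assert np.abs(np.mean(steps) - 5.0) < 0.05
    assert truth.of_kind("mito").speed_um_s.iloc[0] == pytest.approx(1.0)


def test_out_of_tunnel_speed_rejected():
    with pytest.raises(ValueError, match="cannot stay inside"):
        gen_mito_series(small_params(speeds=(5.0,), n_frames=60,
                                     tunnel_length_um=60.0))


def test_injected_patch_has_exact_area():
    p = small_params(n_stationary=0, n_motile=0, tunnel_width_px=50,
                     injected_patch_areas_um2=(4.0, 6.0))
    _, truth = gen_mito_series(p)
    patches = truth.of_kind("patch")
    assert np.allclose(patches.area_um2, [4.0, 6.0], atol=0.08)


# ---------------------------------------------------------------------------
# neurites
# ---------------------------------------------------------------------------

def test_zero_neurites_blank_truth():
    p = SimParams(seed=1, n_neurites=0, n_termini=0)
    _, truth = gen_neurite_image(p)
    assert len(truth) == 0


def test_single_neurite_has_two_termini():
    p = SimParams(seed=1, n_neurites=1)
    _, truth = gen_neurite_image(p)
    assert len(truth.of_kind("bouton")) == 2


@pytest.mark.parametrize("n_neurites,n_termini", [(3, 7), (3, 9), (2, 4), (5, 12)])
def test_terminus_count_matches_path_graph(n_neurites, n_termini):
    """Termini = 2 per path + 1 per branch, the path-graph terminus count."""
    p = SimParams(seed=2, n_neurites=n_neurites, n_termini=n_termini)
    _, truth = gen_neurite_image(p)
    assert len(truth.of_kind("bouton")) == n_termini


def test_too_few_termini_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        gen_neurite_image(SimParams(seed=0, n_neurites=3, n_termini=4))


# ---------------------------------------------------------------------------
# synapse channels
# ---------------------------------------------------------------------------

def test_no_overlaps_channels_disjoint():
    p = SimParams(seed=5, overlap_diameters_um=(), n_puncta=8, noise_sigma=0.0,
                  background_ramp=0.0)
    a, b, truth = gen_synapse_channels(p)
    mask_a = a.pixels > p.background + 0.5 * p.amplitude
    mask_b = b.pixels > p.background + 0.5 * p.amplitude
    assert not (mask_a & mask_b).any()
    assert len(truth.of_kind("overlap")) == 0


def test_overlap_sizes_from_pixel_count_oracle():
    p = SimParams(seed=6, overlap_diameters_um=(1.0, 1.0, 1.0, 1.0), n_puncta=4)
    _, _, truth = gen_synapse_channels(p)
    overlaps = truth.of_kind("overlap")
    assert len(overlaps) == 4
    # equivalent diameter recomputed from the recorded pixel area
    eq = 2 * np.sqrt(overlaps.area_um2 / np.pi)
    assert np.allclose(eq, overlaps.eq_diam_um)
    assert np.allclose(overlaps.eq_diam_um, 1.0, atol=0.15)


def test_oversized_overlap_flagged_against_cutoff():
    p = SimParams(seed=7, overlap_diameters_um=(20.0,), n_puncta=2)
    _, _, truth = gen_synapse_channels(p)
    (row,) = truth.of_kind("overlap").itertuples()
    assert row.exceeds_cutoff
    assert row.eq_diam_um > 15.0


# ---------------------------------------------------------------------------
# z-stacks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("z0,z1,step,expected", [
    (4, 4, 1.0, 1.0),            # single slice
    (3, 11, 0.5, 4.5),           # slice-count oracle: (11-3+1) x 0.5
])
def test_zstack_truth_height(z0, z1, step, expected):
    p = SimParams(seed=3, n_slices=16, z_step=step, signal_slices=(z0, z1))
    _, truth = gen_zstack(p)
    assert truth.meta["height_um"] == pytest.approx(expected)


def test_zstack_44_um_span():
    p = SimParams(seed=3, n_slices=60, z_step=1.0, signal_slices=(5, 48))
    stack, truth = gen_zstack(p)
    assert truth.meta["height_um"] == pytest.approx(44.0)
    assert stack.n_slices == 60


def test_zstack_span_must_fit():
    with pytest.raises(ValueError, match="inside"):
        gen_zstack(SimParams(seed=0, n_slices=10, signal_slices=(5, 12)))


# ---------------------------------------------------------------------------
# MEA recordings
# ---------------------------------------------------------------------------

def test_zero_rate_gives_pure_noise():
    p = SimParams(seed=4, n_channels=2, duration=5.0, firing_rate_hz=0.0)
    rec, truth = gen_mea_recording(p)
    assert len(truth) == 0
    assert abs(rec.traces.std() - p.mea_noise_sigma_uv) < 0.2


def test_seven_minutes_at_ten_khz_is_4p2_million_samples():
    p = SimParams(seed=4, n_channels=1, duration=420.0, firing_rate_hz=0.1)
    rec, _ = gen_mea_recording(p)
    assert rec.n_samples == 4_200_000
    assert rec.duration == pytest.approx(420.0)


def test_coupled_pair_timestamp_arithmetic():
    """Co-spike probability 1: every source spike has a partner 52 ms later."""
    p = SimParams(seed=8, n_channels=2, duration=60.0,
                  firing_rate_hz=(1.0, 0.0),
                  coupled_pairs=((0, 1, 52.0, 1.0),))
    _, truth = gen_mea_recording(p)
    src = truth.objects[truth.objects.electrode == 0].t_s.values
    dst = truth.objects[truth.objects.electrode == 1].t_s.values
    assert len(src) > 20
    matched = sum(np.min(np.abs(dst - (t + 0.052))) < 1e-3 for t in src
                  if t + 0.052 < 60.0 - 0.01)
    assert matched >= 0.98 * len(src)


def test_low_amplitude_warns():
    with pytest.warns(UserWarning, match="underpowered"):
        gen_mea_recording(SimParams(seed=0, n_channels=1, duration=1.0,
                                    spike_amplitude_uv=10.0))


def test_coupling_lag_bounds_validated():
    with pytest.raises(ValueError, match="lag"):
        SimParams(coupled_pairs=((0, 1, 150.0, 1.0),))
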