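"""Parameter-recovery benchmark experiments.

Each function simulates a study-scale synthetic experiment with
:mod:`neuritescope.synth`, runs the corresponding analysis pipeline, and
returns recovery metrics against the simulation truth.  They are shared by
the test suite and by ``scripts/acceptance.py`` so that both always measure
the same, freshly computed quantities.

Study conditions (sample sizes, SNR, speeds, rates) mirror the acquisition
and group statistics of the experiments the pipelines were designed for:
0.639 / 1.296 um/s group-mean transport speeds, 0.06 / 0.139 motile ratios,
50-200 mitochondria per 145-um tunnel segment, 7-minute 10-kHz MEA
recordings at ~1 Hz firing, and 35.38 / 10.83 um group-mean z-stack heights.
"""

from __future__ import annotations

import numpy as np

from . import ephys as E
from . import kymo as K
from . import mito as M
from . import morpho as Mo
from .synth import (
    SimParams,
    gen_mea_recording,
    gen_mito_series,
    gen_neurite_image,
    gen_synapse_channels,
    gen_zstack,
)

#: paper-scale group means used as simulation truth
SPEED_GROUPS_UM_S = {"control": 0.639, "lrrk2": 1.296}
MOTILE_GROUPS = {"control": (2, 31), "lrrk2": (5, 31)}  # (n_motile, n_stationary)
HEIGHT_GROUPS_UM = {"lrrk2": 35.38, "control": 10.83}
Z_STEP_UM = 0.25


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def speed_recovery(seed: int, n_replicates: int = 20) -> dict:
    """Recover the two group-mean transport speeds from tunnel series.

    Each replicate is a 60-frame, 4-tunnel series with 2 motile mitochondria
    per tunnel at the group speed (opposite directions) among 31 stationary
    ones, at SNR 5.
    """
    out = {}
    for gi, (group, v) in enumerate(SPEED_GROUPS_UM_S.items()):
        speeds = []
        for rep in range(n_replicates):
            p = SimParams(seed=_subseed(seed, 10 * gi + 1000 + rep),
                          n_motile=2, n_stationary=31, speeds=(v, -v))
            series, _ = gen_mito_series(p)
            tracks, _, _ = K.analyze_series(series, p.tunnel_rois())
            motile = tracks[tracks.direction.isin(["anterograde", "retrograde"])]
            speeds += motile.speed_um_s.tolist()
        speeds = np.asarray(speeds)
        out[group] = dict(
            truth_um_s=v,
            recovered_um_s=float(speeds.mean()),
            rel_error=float(abs(speeds.mean() - v) / v),
            n_tracks=int(speeds.size),
        )
    return out


def motile_ratio_recovery(seed: int, n_tunnels: int = 20) -> dict:
    """Recover group-mean motile ratios over ``n_tunnels`` tunnels per group.

    Simulated truth: 2 motile / 31 stationary (ratio 0.0606) for the control
    condition and 5 / 31 (0.1389) for the mutant-like condition, speeds drawn
    from the default 0.3-1.8 um/s range.
    """
    out = {}
    n_series = n_tunnels // 4
    for gi, (group, (n_mot, n_stat)) in enumerate(MOTILE_GROUPS.items()):
        ratios, antero = [], []
        for rep in range(n_series):
            p = SimParams(seed=_subseed(seed, 10 * gi + 2000 + rep),
                          n_motile=n_mot, n_stationary=n_stat)
            series, _ = gen_mito_series(p)
            _, summary, _ = K.analyze_series(series, p.tunnel_rois())
            ratios += summary.motile_ratio.tolist()
            antero += summary.anterograde_fraction.dropna().tolist()
        truth = n_mot / (n_mot + n_stat)
        ratios = np.asarray(ratios)
        out[group] = dict(
            truth_ratio=truth,
            recovered_ratio=float(ratios.mean()),
            abs_error=float(abs(ratios.mean() - truth)),
            anterograde_fraction=float(np.mean(antero)) if antero else float("nan"),
            n_tunnels=int(ratios.size),
        )
    return out


def count_recovery(seed: int, counts: tuple[int, ...] = (50, 136, 164, 200)) -> dict:
    """Exact-count recovery for dense puncta fields with the size filter.

    Each run renders the stated number of non-overlapping puncta in a
    145 x 10 um tunnel segment at SNR 5, plus one 4 um^2 disc (must be
    retained) and one 6 um^2 disc (must be rejected by the 5 um^2 rule).
    """
    per_run = []
    filter_ok = True
    for k, n in enumerate(counts):
        p = SimParams(seed=_subseed(seed, 3000 + k), n_tunnels=1, tunnel_width_px=50,
                      n_stationary=n, n_motile=0, n_frames=1, placement="grid",
                      injected_patch_areas_um2=(4.0, 6.0))
        series, truth = gen_mito_series(p)
        roi = p.tunnel_rois()[0]
        det = M.detect_mitochondria(roi.crop_image(series.frame(0)), tunnel_id=roi.tunnel_id)
        expected = n + 1  # puncta + the retained 4 um^2 disc
        per_run.append(dict(truth=n, expected_detections=expected,
                            detected=det.count,
                            n_rejected_area=det.n_rejected_area))
        filter_ok &= det.n_rejected_area >= 1  # the 6 um^2 disc went out
    errors = [abs(r["detected"] - r["expected_detections"]) for r in per_run]
    return dict(
        runs=per_run,
        max_abs_count_error=int(max(errors)),
        exact_fraction=float(np.mean([e == 0 for e in errors])),
        size_filter_correct=bool(filter_ok),
    )


def spike_detection_fidelity(seed: int) -> dict:
    """Recall / precision / timing of spike detection at study scale.

    Twelve channels, 7 minutes at 10 kHz, 5 uV noise, -60 uV spikes at
    ~1 Hz; detected spikes are matched to truth within 0.5 ms.
    """
    p = SimParams(seed=_subseed(seed, 4000))
    rec, truth = gen_mea_recording(p)
    trains = E.detect_spikes(E.bandpass(rec))
    tp, fp, fn = 0, 0, 0
    timing = []
    for c in range(p.n_channels):
        tt = truth.objects[truth.objects.electrode == c].t_s.values
        det = trains[c].times
        used = np.zeros(det.size, bool)
        for t in tt:
            if det.size == 0:
                fn += 1
                continue
            i = int(np.argmin(np.abs(det - t)))
            if abs(det[i] - t) <= 0.5e-3 and not used[i]:
                used[i] = True
                tp += 1
                timing.append(abs(det[i] - t))
            else:
                fn += 1
        fp += int((~used).sum())
    rates = E.mean_firing_rate(trains)
    return dict(
        recall=tp / (tp + fn),
        precision=tp / (tp + fp),
        max_timing_error_ms=float(np.max(timing) * 1e3),
        mean_timing_error_ms=float(np.mean(timing) * 1e3),
        network_mfr_hz=rates.network_mean,
        n_true_spikes=int(len(truth)),
    )


def connectivity_recovery(seed: int) -> dict:
    """Recover an injected 52-ms coupling from a 3-electrode recording.

    One pair is coupled (co-spike probability 0.8); the full pipeline
    (filter, detect, bin, correlate, filter pairs) must find exactly that
    pair, at exactly that lag, with the total network correlation equal to
    the brute-force Pearson r of the pair at the peak lag.
    """
    p = SimParams(seed=_subseed(seed, 5000), n_channels=3,
                  firing_rate_hz=(1.0, 0.3, 1.0),
                  coupled_pairs=((0, 1, 52.0, 0.8),))
    rec, _ = gen_mea_recording(p)
    binned = [E.bin_spikes(t) for t in E.detect_spikes(E.bandpass(rec))]
    cm = E.network_correlation(binned)
    included = cm.pairs[cm.pairs.included]
    row = cm.pairs.iloc[0]  # pair (0, 1)
    lag = int(row.lag_ms)
    a, b = binned[0].counts.astype(float), binned[1].counts.astype(float)
    if lag >= 0:
        oracle_r = float(np.corrcoef(a[: a.size - lag], b[lag:])[0, 1])
    else:
        oracle_r = float(np.corrcoef(a[-lag:], b[: b.size + lag])[0, 1])
    return dict(
        peak_lag_ms=float(row.lag_ms),
        peak_r=float(row.r),
        brute_force_r=oracle_r,
        n_included_pairs=int(len(included)),
        only_coupled_pair_included=bool(
            len(included) == 1 and included.iloc[0].electrode_a == 0
            and included.iloc[0].electrode_b == 1
        ),
        total_network_correlation=cm.total_network_correlation,
    )


def connectivity_null(seed: int, n_pairs: int = 100, n_bins: int = 420_000,
                      rate_hz: float = 1.0) -> dict:
    """Fraction of independent Poisson pairs excluded by the p <= 0.001 filter."""
    p_bin = rate_hz * 1e-3
    excluded = 0
    for k in range(n_pairs):
        rng = np.random.default_rng(_subseed(seed, 6000 + k))
        a = (rng.random(n_bins) < p_bin).astype(np.int64)
        b = (rng.random(n_bins) < p_bin).astype(np.int64)
        lc = E.lagged_correlation(E.BinnedTrain(0, a), E.BinnedTrain(1, b))
        if not (lc.valid and lc.p <= 0.001):
            excluded += 1
    return dict(n_pairs=n_pairs, excluded_fraction=excluded / n_pairs)


def bouton_recovery(seed: int,
                    cases: tuple[tuple[int, int], ...] = ((1, 2), (2, 4), (3, 7),
                                                          (4, 10), (5, 14), (5, 20))) -> dict:
    """Endpoint counts vs path-graph terminus counts on neurite fields."""
    runs = []
    for k, (n_neur, n_term) in enumerate(cases):
        p = SimParams(seed=_subseed(seed, 7000 + k), n_neurites=n_neur, n_termini=n_term)
        img, _ = gen_neurite_image(p)
        res = Mo.count_boutons(img)
        runs.append(dict(truth=n_term, counted=res.n_boutons))
    return dict(
        runs=runs,
        exact_fraction=float(np.mean([r["counted"] == r["truth"] for r in runs])),
    )


def synapse_cutoff_check(seed: int) -> dict:
    """The 15-um cut-off excludes exactly the truth-oversized overlaps."""
    p = SimParams(seed=_subseed(seed, 8000),
                  overlap_diameters_um=(1.0, 1.0, 1.0, 1.0, 20.0))
    chan_a, chan_b, truth = gen_synapse_channels(p)
    res = Mo.synapse_cooccurrence(chan_a, chan_b)
    n_oversized = int(truth.of_kind("overlap").exceeds_cutoff.sum())
    return dict(
        truth_overlaps=int(len(truth.of_kind("overlap"))),
        truth_oversized=n_oversized,
        detected=res.n_overlaps,
        excluded=res.n_excluded,
        mean_size_um=res.mean_size_um,
        cutoff_exact=bool(res.n_excluded == n_oversized
                          and res.n_overlaps == len(truth.of_kind("overlap")) - n_oversized),
    )


def zstack_height_benchmark(seed: int) -> dict:
    """Group-mean stack heights and their ratio (the 'over 3 times' check).

    The group means are simulated as spans on a 0.25-um z grid (35.5 and
    10.75 um) and measured with the height pipeline.
    """
    out = {}
    for k, (group, target) in enumerate(HEIGHT_GROUPS_UM.items()):
        n = round(target / Z_STEP_UM)
        p = SimParams(seed=_subseed(seed, 9000 + k), n_slices=n + 20,
                      z_step=Z_STEP_UM, signal_slices=(8, 8 + n - 1))
        stack, truth = gen_zstack(p)
        res = M.zstack_height(stack)
        out[group] = dict(simulated_um=truth.meta["height_um"],
                          measured_um=res.height_um, group_mean_um=target)
    out["ratio"] = out["lrrk2"]["measured_um"] / out["control"]["measured_um"]
    return out
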