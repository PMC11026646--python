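"""Filtering, spike detection, binning, and lagged-correlation connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuritescope import ephys as E
from neuritescope.synth import SimParams, gen_mea_recording


def _recording(trace_or_traces, fs=10_000.0):
    traces = np.atleast_2d(np.asarray(trace_or_traces, dtype=float))
    return E.RawRecording(traces, fs)


# ---------------------------------------------------------------------------
# band-pass
# ---------------------------------------------------------------------------

def test_passband_tone_preserved():
    """A tone at the geometric band centre (~949 Hz) passes at unit gain."""
    f0 = np.sqrt(300.0 * 3000.0)
    t = np.arange(0, 2.0, 1e-4)
    tone = 40.0 * np.sin(2 * np.pi * f0 * t)
    out = E.bandpass(_recording(tone)).traces[0]
    core = out[5000:-5000]
    assert np.abs(core).max() == pytest.approx(40.0, rel=0.01)


def test_low_frequency_attenuated_at_least_20db():
    # analytic check: |H(10 Hz)| of the 2nd-order 300-3000 Hz Butterworth,
    # squared because filtering is forward-backward
    from scipy.signal import butter, sosfreqz
    sos = butter(2, [300, 3000], btype="bandpass", fs=10_000, output="sos")
    _, h = sosfreqz(sos, worN=[2 * np.pi * 10 / 10_000])
    analytic_db = 20 * np.log10(np.abs(h[0]) ** 2)
    assert analytic_db < -20
    t = np.arange(0, 2.0, 1e-4)
    tone = 40.0 * np.sin(2 * np.pi * 10.0 * t)
    out = E.bandpass(_recording(tone)).traces[0][5000:-5000]
    meas_db = 20 * np.log10(np.abs(out).max() / 40.0)
    assert meas_db < -20


def test_dc_offset_removed():
    out = E.bandpass(_recording(np.full(20_000, 55.0))).traces[0]
    assert abs(out.mean()) < 1e-6


def test_low_sampling_rate_rejected():
    with pytest.raises(ValueError, match="band edge"):
        E.bandpass(_recording(np.zeros(1000), fs=5000.0))


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def test_threshold_is_median_minus_five_sd():
    rng = np.random.default_rng(0)
    trace = rng.normal(0, 4.0, 200_000)
    trace = (trace - np.median(trace)) * (4.0 / trace.std())
    theta = E.detection_threshold(trace)
    assert theta == pytest.approx(np.median(trace) - 5 * trace.std())
    assert theta == pytest.approx(-20.0, abs=0.05)


def test_all_zero_trace_no_spikes():
    trains = E.detect_spikes(_recording(np.zeros(10_000)))
    assert trains[0].n_spikes == 0


def test_detection_recall_precision_on_short_recording():
    p = SimParams(seed=12, n_channels=2, duration=30.0)
    rec, truth = gen_mea_recording(p)
    trains = E.detect_spikes(E.bandpass(rec))
    for c in (0, 1):
        tt = truth.objects[truth.objects.electrode == c].t_s.values
        det = trains[c].times
        assert abs(len(det) - len(tt)) <= 1
        for t in tt:
            assert np.min(np.abs(det - t)) <= 0.5e-3


def test_dead_time_suppresses_double_triggers():
    fs = 10_000.0
    trace = np.zeros(5000)
    trace[1000:1004] = -100.0  # one broad event crossing threshold twice
    trace[1006:1009] = -90.0
    trace += np.sin(np.arange(5000)) * 1.0  # give it nonzero SD
    trains = E.detect_spikes(_recording(trace, fs))
    assert trains[0].n_spikes == 1


# ---------------------------------------------------------------------------
# rates and binning
# ---------------------------------------------------------------------------

def test_mean_firing_rate_arithmetic():
    train = E.SpikeTrain(0, np.linspace(0.5, 419.5, 420), 420.0)
    rates = E.mean_firing_rate([train], 420.0)
    assert rates.per_electrode.rate_hz.iloc[0] == pytest.approx(1.0)
    empty = E.mean_firing_rate([E.SpikeTrain(0, np.empty(0), 420.0)], 420.0)
    assert empty.network_mean == 0.0


def test_network_mfr_close_to_poisson_truth():
    p = SimParams(seed=13, n_channels=8, duration=60.0, firing_rate_hz=0.5)
    rec, _ = gen_mea_recording(p)
    rates = E.mean_firing_rate(E.detect_spikes(E.bandpass(rec)))
    se = np.sqrt(0.5 / 60.0 / 8)  # Poisson SE of the network mean
    assert abs(rates.network_mean - 0.5) < 3 * se


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=9.999), max_size=60))
def test_binning_conserves_spike_count(times):
    times = np.unique(np.asarray(times))
    train = E.SpikeTrain(0, times, 10.0)
    binned = E.bin_spikes(train, 1.0)
    assert binned.n_spikes == train.n_spikes
    assert binned.n_bins == 10_000


# ---------------------------------------------------------------------------
# lagged correlation
# ---------------------------------------------------------------------------

def test_self_correlation_peaks_at_zero():
    rng = np.random.default_rng(2)
    a = rng.poisson(0.4, 5000)
    lc = E.lagged_correlation(E.BinnedTrain(0, a), E.BinnedTrain(1, a))
    assert lc.peak_lag_ms == 0.0
    assert lc.peak_r == pytest.approx(1.0)


def test_shifted_train_recovers_the_shift():
    rng = np.random.default_rng(3)
    a = (rng.random(50_000) < 0.002).astype(int)
    b = np.roll(a, 52)
    lc = E.lagged_correlation(E.BinnedTrain(0, a), E.BinnedTrain(1, b))
    assert lc.peak_lag_ms == 52.0
    assert lc.peak_r > 0.99
    assert lc.p < 1e-6


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_lag_symmetry_small_trains(seed):
    """r(a,b) at lag L equals r(b,a) at -L, exhaustively on small trains."""
    rng = np.random.default_rng(seed)
    a = rng.poisson(0.5, 400)
    b = rng.poisson(0.5, 400)
    _, r_ab, _ = E.pearson_by_lag(a, b, 30)
    _, r_ba, _ = E.pearson_by_lag(b, a, 30)
    np.testing.assert_allclose(r_ab, r_ba[::-1], atol=1e-12)


def test_pearson_by_lag_matches_naive_corrcoef():
    rng = np.random.default_rng(4)
    a = rng.poisson(0.6, 600)
    b = rng.poisson(0.6, 600)
    lags, r, _ = E.pearson_by_lag(a, b, 25)
    for L in (-25, -7, 0, 3, 25):
        if L >= 0:
            x, y = a[: 600 - L], b[L:]
        else:
            x, y = a[-L:], b[: 600 + L]
        assert r[L + 25] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


def test_zero_variance_train_flagged_invalid():
    lc = E.lagged_correlation(E.BinnedTrain(0, np.zeros(5000, int)),
                              E.BinnedTrain(1, np.ones(5000, int)))
    assert not lc.valid


def _circular_permutation_peak_null(a, b, max_lag, n_perm, rng):
    """Permutation null of the peak r via circular shifts of one train.

    A circular shift by s then a scan over lags [-L, L] is the same as
    scanning the full circular correlation over the window [s-L, s+L], so
    the whole null distribution comes from one FFT-based circular
    correlation plus window maxima.
    """
    n = a.size
    af = a - a.mean()
    bf = b - b.mean()
    denom = n * af.std() * bf.std()
    circ = np.fft.irfft(np.conj(np.fft.rfft(af)) * np.fft.rfft(bf), n) / denom
    peaks = np.empty(n_perm)
    shifts = rng.integers(2 * max_lag + 1, n - 2 * max_lag - 1, n_perm)
    for i, s in enumerate(shifts):
        window = circ[(s + np.arange(-max_lag, max_lag + 1)) % n]
        peaks[i] = window.max()
    return peaks


def test_peak_p_value_consistent_with_permutation_oracle():
    """On independent trains the analytic (Sidak/hypergeometric) significance
    decision agrees with a circular-shift permutation null."""
    rng = np.random.default_rng(5)
    n, max_lag = 60_000, 100
    analytic_sig, perm_sig = 0, 0
    for _ in range(20):
        a = (rng.random(n) < 0.002).astype(int)
        b = (rng.random(n) < 0.002).astype(int)
        lc = E.lagged_correlation(E.BinnedTrain(0, a), E.BinnedTrain(1, b))
        peaks = _circular_permutation_peak_null(a, b, max_lag, 400, rng)
        p_perm = (1 + np.sum(peaks >= lc.peak_r)) / 401
        analytic_sig += lc.p <= 0.05
        perm_sig += p_perm <= 0.05
    # both should call (almost) nothing significant at the 5% level, and
    # agree with each other within Monte-Carlo error
    assert analytic_sig <= 3
    assert perm_sig <= 3
    assert abs(analytic_sig - perm_sig) <= 2


def test_coupled_trains_significant_under_both_analytic_and_permutation():
    rng = np.random.default_rng(6)
    n = 60_000
    a = (rng.random(n) < 0.002).astype(int)
    b = np.zeros(n, int)
    idx = np.flatnonzero(a) + 40
    b[idx[idx < n]] = 1
    b |= (rng.random(n) < 0.001).astype(int)
    lc = E.lagged_correlation(E.BinnedTrain(0, a), E.BinnedTrain(1, b))
    assert lc.peak_lag_ms == 40.0
    assert lc.p < 1e-6
    peaks = _circular_permutation_peak_null(a, b, 100, 400, rng)
    assert (1 + np.sum(peaks >= lc.peak_r)) / 401 < 0.01


# ---------------------------------------------------------------------------
# network correlation
# ---------------------------------------------------------------------------

def _binned_from_times(electrode, times, duration=60.0):
    return E.bin_spikes(E.SpikeTrain(electrode, np.asarray(times), duration))


def test_activity_filter_boundary_at_ten_spikes():
    nine = _binned_from_times(0, np.linspace(1, 50, 9))
    ten = _binned_from_times(1, np.linspace(1, 50, 10))
    other = _binned_from_times(2, np.linspace(0.5, 55, 40))
    cm = E.network_correlation([nine, ten, other])
    assert cm.active_electrodes == [1, 2]
    assert set(zip(cm.pairs.electrode_a, cm.pairs.electrode_b)) == {(1, 2)}


def test_all_inactive_flagged():
    quiet = [_binned_from_times(i, [1.0 * i + 0.5]) for i in range(3)]
    with pytest.warns(UserWarning, match="fewer than 2 active"):
        cm = E.network_correlation(quiet)
    assert not cm.valid
    assert np.isnan(cm.total_network_correlation)


def test_only_coupled_pair_included_and_total_matches_oracle():
    rng = np.random.default_rng(7)
    n = 120_000  # 120 s at 1 ms bins
    a = (rng.random(n) < 0.002).astype(int)
    b = np.zeros(n, int)
    idx = np.flatnonzero(a) + 52
    b[idx[idx < n]] = 1
    c = (rng.random(n) < 0.002).astype(int)
    trains = [E.BinnedTrain(0, a), E.BinnedTrain(1, b), E.BinnedTrain(2, c)]
    cm = E.network_correlation(trains)
    included = cm.pairs[cm.pairs.included]
    assert len(included) == 1
    row = included.iloc[0]
    assert (row.electrode_a, row.electrode_b) == (0, 1)
    assert row.lag_ms == 52.0
    oracle = np.corrcoef(a[: n - 52], b[52:])[0, 1]
    assert cm.total_network_correlation == pytest.approx(oracle, abs=1e-12)


def test_fewer_than_two_trains_rejected():
    with pytest.raises(ValueError):
        E.network_correlation([_binned_from_times(0, np.linspace(1, 50, 30))])
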