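"""Synthetic MEA recordings: Gaussian noise plus injected spike waveforms.

Each channel is white Gaussian noise (in microvolts) with a fixed biphasic,
dominant-negative 1-ms spike template added at Poisson event times.  Coupled
channel pairs share co-spikes offset by a stated lag, which is what the
lagged-correlation stage is meant to recover.  Truth records hold the
rendered trough time of every spike, aligned to the sample grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..ephys import RawRecording
from .params import SimParams
from .truth import GroundTruth


def spike_template(sampling_rate: float, amplitude_uv: float) -> tuple[np.ndarray, int]:
    """Fixed 1-ms biphasic template; returns (waveform, trough index)."""
    n = max(int(round(1.0e-3 * sampling_rate)), 7)
    t_ms = (np.arange(n) + 0.5) / sampling_rate * 1e3
    w = -np.exp(-((t_ms - 0.30) ** 2) / (2 * 0.08**2)) \
        + 0.32 * np.exp(-((t_ms - 0.65) ** 2) / (2 * 0.12**2))
    w *= amplitude_uv / abs(w.min())
    return w, int(np.argmin(w))


def _poisson_train(rng: np.random.Generator, rate: float, t_lo: float, t_hi: float,
                   refractory_s: float) -> np.ndarray:
    if rate <= 0 or t_hi <= t_lo:
        return np.empty(0)
    n = rng.poisson(rate * (t_hi - t_lo))
    times = np.sort(rng.uniform(t_lo, t_hi, n))
    kept: list[float] = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.array(kept)


def gen_mea_recording(params: SimParams) -> tuple[RawRecording, GroundTruth]:
    """Render a multi-channel recording; truth lists every injected spike.

    Coupled pairs (source, target, lag ms, probability) add a co-spike on
    the target ``lag`` after each source spike with the stated probability.
    A refractory pass removes collisions, and only spikes actually rendered
    enter the truth.
    """
    fs = params.sampling_rate
    dur = params.duration
    if not dur > 0:
        raise ValueError("duration must be positive")
    if not params.spike_amplitude_uv > 0:
        raise ValueError("spike amplitude must be positive")
    if params.spike_amplitude_uv < 5 * params.mea_noise_sigma_uv:
        warnings.warn(
            "spike amplitude is below 5x the noise sigma; detection will be underpowered"
        )
    n_samples = int(round(dur * fs))
    n_ch = params.n_channels
    rates = params.firing_rate_hz
    if np.isscalar(rates):
        rates = [float(rates)] * n_ch
    if len(rates) != n_ch:
        raise ValueError("need one firing rate per channel")

    template, trough = spike_template(fs, params.spike_amplitude_uv)
    refractory = params.refractory_ms * 1e-3
    guard = (len(template) + 2) / fs
    t_lo, t_hi = guard, dur - guard

    base: list[np.ndarray] = [
        _poisson_train(params.rng_for("mea", c), rates[c], t_lo, t_hi, refractory)
        for c in range(n_ch)
    ]
    extra: list[list[float]] = [[] for _ in range(n_ch)]
    for k, (src, dst, lag_ms, prob) in enumerate(params.coupled_pairs):
        rng_c = params.rng_for("mea-couple", k)
        for t in base[src]:
            if rng_c.random() < prob:
                tt = t + lag_ms * 1e-3
                if t_lo <= tt <= t_hi:
                    extra[dst].append(tt)

    traces = np.empty((n_ch, n_samples), dtype=np.float32)
    records: list[dict] = []
    for c in range(n_ch):
        times = np.sort(np.concatenate([base[c], np.array(extra[c])]))
        kept: list[int] = []
        last = -np.inf
        for t in times:
            idx = int(round(t * fs))
            if idx / fs - last >= refractory:
                kept.append(idx)
                last = idx / fs
        noise_rng = params.rng_for("mea-noise", c)
        trace = noise_rng.normal(0.0, params.mea_noise_sigma_uv, n_samples)
        for idx in kept:
            start = idx - trough
            trace[start : start + len(template)] += template
            records.append(dict(kind="spike", electrode=c, t_s=idx / fs))
        traces[c] = trace

    channel_map = pd.DataFrame({
        "electrode": np.arange(n_ch),
        "chamber": ["top" if c < n_ch // 2 else "bottom" for c in range(n_ch)],
    })
    truth = GroundTruth(
        pd.DataFrame(records, columns=["kind", "electrode", "t_s"]),
        meta={
            "scene": "mea",
            "sampling_rate": fs,
            "duration": dur,
            "coupled_pairs": [list(p) for p in params.coupled_pairs],
        },
    )
    return RawRecording(traces, fs, channel_map), truth
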