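"""MEA spike detection and lagged-correlation functional connectivity.

Simulates a three-electrode extracellular recording (7 min at 10 kHz) where
one pair co-spikes at a 52-ms lag, then runs the full chain: zero-phase
Butterworth band-pass, -5 SD threshold detection, 1-ms binning, pairwise
peak-lag Pearson correlation with the activity (>= 10 spikes) and
significance (p <= 0.001) filters.
"""

from neuritescope import ephys
from neuritescope.synth import SimParams, gen_mea_recording

params = SimParams(seed=15, n_channels=3, firing_rate_hz=(1.0, 0.3, 1.0),
                   coupled_pairs=((0, 1, 52.0, 0.8),))
recording, truth = gen_mea_recording(params)

filtered = ephys.bandpass(recording)
trains = ephys.detect_spikes(filtered)
rates = ephys.mean_firing_rate(trains)
binned = [ephys.bin_spikes(t) for t in trains]
matrix = ephys.network_correlation(binned)

print(f"Detected spikes per electrode: {[t.n_spikes for t in trains]} "
      f"(truth: {len(truth)} total)")
print(f"Network mean firing rate: {rates.network_mean:.3f} +- {rates.network_sd:.3f} Hz")
print("\nPairwise peak-lag correlations:")
print(matrix.pairs.to_string(index=False))
print(f"\nTotal network correlation: {matrix.total_network_correlation:.4f}")
print("Only the injected 52-ms coupling survives the p <= 0.001 filter; the")
print("total network correlation is the mean peak r over surviving pairs.")
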