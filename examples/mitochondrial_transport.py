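"""Kymograph analysis of axonal mitochondrial transport.

Simulates a one-minute TMRM time-lapse of four 145-um microtunnel segments
(one frame per second) containing stationary and motile mitochondria, builds
a kymograph per tunnel, suppresses the stationary stripes, detects the
slanted-line trajectories, and prints per-tunnel motility summaries next to
the simulation truth.
"""

import numpy as np

from neuritescope import kymo
from neuritescope.synth import SimParams, gen_mito_series

params = SimParams(seed=11, n_tunnels=4, n_stationary=31, n_motile=2,
                   speeds=(1.296, -1.296))
series, truth = gen_mito_series(params)
tracks, summary, _ = kymo.analyze_series(series, params.tunnel_rois())

print("Per-tunnel motility (truth: 2 motile at 1.296 um/s, 31 stationary):")
print(summary[["tunnel", "n_motile", "n_stationary", "motile_ratio",
               "mean_speed_um_s"]].to_string(index=False))

motile = tracks[tracks.direction.isin(["anterograde", "retrograde"])]
err = abs(motile.speed_um_s.mean() - 1.296) / 1.296
print(f"\nMean recovered speed: {motile.speed_um_s.mean():.3f} um/s "
      f"({100 * err:.1f}% from the simulated 1.296 um/s)")
print("The motile ratio is n_motile / (n_motile + n_stationary) per tunnel;")
print("speeds come from the fitted slope of each kymograph line.")
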