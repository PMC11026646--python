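"""Counting TMRM-labelled mitochondria in a tunnel segment.

Renders a dense field of non-overlapping puncta (plus two calibration discs
of exactly 4 and 6 um^2), runs the detection chain — smooth, top-hat, robust
threshold, 8-connected components, artifact rejection — and shows that the
5 um^2 size rule removes exactly the oversized disc.
"""

import numpy as np

from neuritescope import mito
from neuritescope.synth import SimParams, gen_mito_series

params = SimParams(seed=12, n_tunnels=1, tunnel_width_px=50, n_stationary=136,
                   n_motile=0, n_frames=1, placement="grid",
                   injected_patch_areas_um2=(4.0, 6.0))
series, truth = gen_mito_series(params)
roi = params.tunnel_rois()[0]
det = mito.detect_mitochondria(roi.crop_image(series.frame(0)))

print(f"Simulated: 136 mitochondria + discs of 4 and 6 um^2")
print(f"Detected:  {det.count} objects "
      f"(expected 137: the puncta plus the retained 4 um^2 disc)")
print(f"Rejected by the 5 um^2 size rule: {det.n_rejected_area}")
print(f"Median detected size: {np.median(det.sizes_um2):.2f} um^2 "
      f"(truth half-maximum footprint: {truth.of_kind('mito').area_um2.iloc[0]:.2f} um^2)")
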