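"""Pre/post-synaptic marker co-occurrence with the 15-um cut-off.

Renders two puncta channels (presynaptic and postsynaptic markers) with
four 1-um co-located contacts and one 20-um artifact, thresholds each
channel (Otsu / Triangle), takes the AND of the masks, and counts overlap
particles below the 15-um equivalent-diameter cut-off.
"""

from neuritescope import morpho
from neuritescope.synth import SimParams, gen_synapse_channels

params = SimParams(seed=14, overlap_diameters_um=(1.0, 1.0, 1.0, 1.0, 20.0))
presynaptic, postsynaptic, truth = gen_synapse_channels(params)
result = morpho.synapse_cooccurrence(presynaptic, postsynaptic)

overlaps = truth.of_kind("overlap")
print(f"Simulated overlaps: {len(overlaps)} "
      f"(of which {int(overlaps.exceeds_cutoff.sum())} exceeds the 15-um cut-off)")
print(f"Counted synaptic contacts: {result.n_overlaps}")
print(f"Excluded as oversized: {result.n_excluded}")
print(f"Mean contact size: {result.mean_size_um:.2f} um equivalent diameter")
print("Co-occurrence of the two markers is the proxy for a synaptic contact;")
print("the cut-off removes stain aggregates that are too large to be synapses.")
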