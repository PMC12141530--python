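"""Basal mRNA fraction: how deep does RNA sit in the BM-attached layer?

Generates a synthetic tissue layer whose RNA spot depth follows a
truncated-exponential law (strong basal enrichment), then measures the
10-bin apico-basal intensity profile and the basal fraction, and compares
against the closed-form expectation.
"""

import numpy as np

import epiquant as eq

image, layer, truth = eq.generate_layer_section(
    shape=(260, 220), depth_law="exponential", tau=0.2,
    n_spots=50_000, noise_sd=0.0, seed=42,
)

depth = eq.compute_depth_field(layer)
rna = eq.subtract_background(image.channel("rna"), layer.mask, background=0.0)
profile = eq.bin_intensity_profile(rna, depth, n_bins=10)
fraction = eq.basal_mrna_fraction(profile, basal_cutoff=0.3)

print("per-bin intensity fractions (basal-most bin first):")
print(np.array2string(profile.fractions, precision=3))
print(f"measured basal fraction : {fraction:.4f}")
print(f"closed-form expectation : {truth.expected['basal_fraction'].value:.4f}")
print()
print("The basal fraction is the share of RNA fluorescence in the bottom")
print("30% of the layer depth; 0.30 would mean no basal enrichment, and")
print("values near 0.78 reflect the tau=0.2 exponential concentration at")
print("the basement membrane.")
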