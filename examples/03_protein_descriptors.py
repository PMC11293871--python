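"""Compute the 576-dimensional protein sequence descriptor.

20 monopeptide frequencies + 400 dipeptide frequencies + 156
physicochemical features, with optional L2 normalization.
"""

import numpy as np

from dtre.seq_features import compute_descriptors, l2_normalize, physchem_feature_names

seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKR"
vec = compute_descriptors(seq)
names = physchem_feature_names()

print(f"sequence length {len(seq)} -> descriptor of {vec.values.shape[0]} values")
print(f"monopeptide block sums to {vec.monopeptide.sum():.3f}")
print(f"dipeptide block sums to   {vec.dipeptide.sum():.3f}")
for feat in ("length", "molecular_weight", "gravy", "isoelectric_point"):
    print(f"{feat:<18}{vec.physchem[names.index(feat)]:.3f}")

unit = l2_normalize(vec)
print(f"L2-normalized norm: {np.linalg.norm(unit.values):.6f}")
# The frequency blocks are exact relative frequencies (each sums to 1);
# the physicochemical block mixes whole-sequence properties with
# distribution statistics of 14 per-residue property scales.
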