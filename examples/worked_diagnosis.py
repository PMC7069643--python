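"""Diagnose the most imbalanced specimen of the potato survey.

The observed composition and its nearest balanced (true-negative) reference
are published alongside the survey; this script recomputes the corrective
perturbation vector, the Aitchison distance and the nutrient ranking.
"""

import numpy as np

from ionodiag import aitchison_distance, perturb, perturbation_difference
from ionodiag.coda import NUTRIENTS, clr_transform, ClrVector, rank_imbalance, subcomposition
from ionodiag.worked_example import OBSERVED, REFERENCE

pert = perturbation_difference(OBSERVED, REFERENCE)
dist = aitchison_distance(OBSERVED, REFERENCE)

print("observed composition :", np.round(OBSERVED.values, 4), OBSERVED.parts)
print("reference composition:", np.round(REFERENCE.values, 4))
print("perturbation vector  :", np.round(pert.values, 4))
print("Aitchison distance (5 nutrients):", round(dist, 4))

check = perturb(OBSERVED, pert)
print("observed ⊕ perturbation reaches reference:",
      np.allclose(check.values, REFERENCE.values, atol=1e-12))

q5 = clr_transform(subcomposition(OBSERVED, NUTRIENTS))
r5 = clr_transform(subcomposition(REFERENCE, NUTRIENTS))
print("\nnutrients ranked by apparent imbalance (largest correction first):")
for entry in rank_imbalance(ClrVector(r5.values - q5.values, NUTRIENTS)):
    print(f"  {entry.part:<2} {entry.status:<9} |clr delta| = {entry.magnitude:.3f}")

# The perturbation vector is the multiplicative translation on the simplex
# that rebalances the specimen; parts above 1/6 must increase relative to
# the rest (deficient), parts below 1/6 decrease (excess).
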