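"""A comparator with an AHL-programmable detection threshold.

Driving the reverse branch with AHL while sweeping Arabinose on the forward
branch shifts the half-max input (the detection threshold) upward with AHL.
In the refined luxA-luxC split, operated below threshold, the reverse drive
cancels out of the ON/OFF ratio, so the fold change stays constant while
the threshold moves.
"""

import numpy as np

from luxcircuit import LuxReactionParams, PromoterParams, comparator_transfer
from luxcircuit.fitting import threshold_series

p_bad = PromoterParams(K=1.0, basal=0.02)
p_lux = PromoterParams(K=1.0, basal=0.02)
arab = np.logspace(-3, 3, 60)

print("luxA-luxC comparator, threshold vs AHL co-input:")
curves = {
    ahl: comparator_transfer(arab, ahl, "luxA-luxC", p_bad, p_lux, LuxReactionParams())
    for ahl in (0.5, 1.0, 2.0, 4.0)
}
for ahl, thr in threshold_series(curves):
    print(f"  AHL={ahl:3.1f} -> detection threshold = {thr:.3f} (Arabinose units)")
print("  -> the threshold is programmable: it rises with the reverse drive.\n")

print("fold change (ON/OFF) in the sub-threshold regime (K_R large):")
lux = LuxReactionParams(K_R=1000.0)
for ahl in (0.5, 4.0):
    dr = comparator_transfer(arab, ahl, "luxA-luxC", p_bad, p_lux, lux)
    print(f"  AHL={ahl:3.1f} -> fold change = {dr.outputs.max() / dr.outputs.min():.2f}")
print(f"  -> both match 1/basal = {1 / p_bad.basal:.0f}: the reverse drive")
print("     cancels, so changing the threshold does not change the ON/OFF span.")
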