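"""Power-law transfer function of the intact luxCDABE operon.

When one promoter drives all five genes, luciferase (a LuxA-LuxB dimer)
rises as the square of the drive while the reverse enzymes rise linearly.
The steady-state intensity then follows a local power law I ~ x^n whose
exponent stays strictly between 1 and 2 — a graded, saturation-free
response no fluorescent reporter gives.
"""

import numpy as np

from luxcircuit import (
    LuxReactionParams,
    local_loglog_slope,
    wildtype_operon_response,
)
from luxcircuit.fitting import fit_power_law

x = np.logspace(-3, 3, 200)
dr = wildtype_operon_response(x, LuxReactionParams())
slopes = local_loglog_slope(dr)

print(f"local log-log slope over x in [1e-3, 1e3] ({len(x)} points):")
print(f"  max slope = {slopes.max():.4f}  (-> 2 as x -> 0)")
print(f"  min slope = {slopes.min():.4f}  (-> 1 as x -> infinity)")

mid = (x > 0.1) & (x < 10)
fit = fit_power_law(x[mid], dr.outputs[mid])
print(f"single power-law fit over the mid-range window x in [0.1, 10]:")
print(f"  I ~ x^{fit.n:.3f}  (R^2 = {fit.r2:.5f})")
print("  -> the exponent sits inside (1, 2): the operon converts a")
print("     saturating promoter input into an unsaturated power law.")
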