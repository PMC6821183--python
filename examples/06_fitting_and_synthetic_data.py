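"""Hill fitting of noisy synthetic plate-reader data.

Generates triplicate dose-response wells from a known Hill curve with 10%
multiplicative noise and OD600 variation, normalizes by OD, averages the
replicates and refits — the standard analysis loop for inducible-promoter
characterization — then reports a Monte-Carlo recovery rate.
"""

import numpy as np

from luxcircuit import DoseResponse, HillFit, fit_hill
from luxcircuit.fitting import hill_recovery_study
from luxcircuit.synth import generate_dose_response

true = HillFit(vmax=1.0, K=30.0 ** (1 / 1.5), n=1.5, basal=0.0, rss=0.0, success=True)
grid = np.logspace(-1, 3, 9)

ds = generate_dose_response(true, grid, noise_cv=0.1, seed=42, replicates=3)
mean = ds.normalized().groupby("condition")["lum_norm"].mean()
fit = fit_hill(DoseResponse(mean.index.to_numpy(), mean.to_numpy()))

print(f"true curve:   n={true.n:.2f}  K={true.K:.2f}  (aggregate K^n={true.khat:.1f})")
print(f"fitted curve: n={fit.n:.2f}  K={fit.K:.2f}  (aggregate K^n={fit.khat:.1f})")
print()

res = hill_recovery_study(n_trials=200, seed=0)
print(f"Monte-Carlo recovery over {res['n_trials']} trials "
      f"(K within 15%, n within 0.2): {100 * res['recovery_rate']:.1f}%")
print("-> triplicate wells at 10% CV are enough to pin down a Hill")
print("   transfer function measured over four decades of inducer.")
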