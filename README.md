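# luxcircuit

Kinetic and circuit models of engineered *luxCDABE* bioluminescent
biosensors, for synthetic biologists who want to reason quantitatively
about split-operon designs before (or instead of) building them.

The bacterial bioluminescence cassette is more than a reporter: luciferase
(LuxAB, level `E_F`) burns an aldehyde pool `S` into fatty acid `P`,
emitting light, while LuxCDE (level `E_R`) regenerates the aldehyde.
Modelling both directions,

    dP/dt = K_F·E_F·S − K_R·E_R·P,   S + P = S_T,

gives a steady-state light output

    I ∝ E_R · (E_F/K_deff) / (1 + E_F/K_deff),   K_deff = K_R·E_R/K_F,

so the reverse branch programs **both** the detection threshold `K_deff`
and the saturating intensity. `luxcircuit` builds the circuit repertoire
that follows from this:

* **Wild-type operon reporter** — one promoter drives all five genes
  (`E_F ∝ x²`, `E_R ∝ x`), producing a power-law response `I ∝ x^n` with
  `1 < n < 2` that never saturates at realistic inputs.
* **MIN fuzzy lattice / AND gate** — splitting luxAB and luxCDE under two
  inducers makes the output a soft minimum `ab/(a+b)` of the two branches;
  gates are scored by the output dynamic range
  `ODR = min_OFF log₁₀(I_ON/I_OFF)`.
* **Comparator** — AHL on the reverse branch shifts the half-max Arabinose
  input (a programmable detection threshold) while, below threshold, the
  ON/OFF fold change stays fixed.
* **Stress-promoter dynamics** — delayed rise-and-decay responses
  `I(t) = X0·(1−e^{−(t−τ_D1)/τ_eff})·(e^{−(t−τ_D2)/τ_1}+β)+c` for recA and
  katG, with crosstalk modelled as pulse summation.
* **Crosstalk-compensating circuit** — an incoherent feedforward loop
  (katG → AHL → TetR ⊣ luxAB, recA → luxCDE) that makes the number of
  bioluminescent peaks count the number of chemicals present, and acts as
  NIMPLY logic at steady state.
* **Fitting and synthetic data** — Hill/power-law fits in log space,
  threshold extraction, and a seeded plate-reader-like generator
  (triplicates, OD600 normalization, multiplicative noise, 15-min cadence).

## Worked example

```python
import numpy as np
from luxcircuit import (LuxReactionParams, wildtype_operon_response,
                        local_loglog_slope, count_peaks, iffl_simulate)

x = np.logspace(-3, 3, 200)
slopes = local_loglog_slope(wildtype_operon_response(x, LuxReactionParams()))
print(slopes.min(), slopes.max())   # 1.0011 1.9989

for doses in (("NA",), ("H2O2",), ("NA", "H2O2")):
    print(doses, count_peaks(iffl_simulate(doses)))
# ('NA',) 1   ('H2O2',) 1   ('NA', 'H2O2') 2
```

The slope bounds say the intact operon's transfer function is a local power
law with exponent strictly between 1 (reverse-limited) and 2 (dimer-limited)
— amplification without saturation. The peak counts show the feedforward
circuit converting "which chemicals are present" into "how many peaks".

The `examples/` directory holds one short narrative script per capability
(kinetics, power law, logic gates, comparator, stress/IFFL dynamics,
fitting on synthetic data); each prints the numbers it computes and what
they mean. A thin CLI mirrors the main entry points:

```bash
luxcircuit gate-eval --gate min          # truth table + ODR
luxcircuit biosensor-sim --chemicals NA,H2O2
luxcircuit run examples/iffl_scenario.yaml   # scenario runs from YAML
```

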