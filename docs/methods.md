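# Methods

## The model

`luxcircuit` models the bacterial bioluminescence cassette *luxCDABE* as a
reversible two-enzyme metabolic reaction rather than as a plain reporter.
Luciferase (the LuxA–LuxB dimer, expression level `E_F`) oxidizes a
long-chain aldehyde `S` to the fatty acid `P`, emitting light; the
reductase/transferase/synthetase complex (LuxCDE, level `E_R`) regenerates
the aldehyde:

    dP/dt = K_F·E_F·S − K_R·E_R·P,     S + P = S_T  (conserved pool)

At steady state `P = S_T·(E_F/K_deff)/(1 + E_F/K_deff)` with
`K_deff = K_R·E_R/K_F`. Assuming the reduced-flavin pool `Y_T` is never
significantly depleted (`Y_T ≫ Y*`; no depletion correction is modelled),
the emitted intensity is proportional to the forward flux, and at steady
state

    I = (S_T·Y_T·K_R/K_d) · E_R · (E_F/K_deff)/(1 + E_F/K_deff).

Two consequences drive everything else in the package:

* `K_deff` is a *programmable detection threshold*: `I` reaches half its
  `E_F → ∞` plateau exactly at `E_F = K_deff`, and the plateau itself is
  proportional to `E_R`. Threshold and saturation level are set together by
  the reverse branch.
* Rewriting `I ∝ E_F·E_R/(K_F·E_F + K_R·E_R)` (the division-safe form used
  in the code) exposes the output as a *soft minimum* of the two branches —
  the basis of the MIN fuzzy-lattice AND gate.

## Units and numerical choices

Time is in minutes, concentrations in arbitrary consistent units, signal in
a.u.; all five rate/affinity constants default to 1 (no absolute values are
published for them) and the global proportionality constant of the
intensity model (`signal_scale`) defaults to 1. The reaction ODE is linear,
so `solve_ivp` (LSODA, rtol 1e-8, atol 1e-10) resolves it essentially to
machine precision; tests compare trajectories against the closed-form
exponential relaxation `P(t) = P∞(1 − e^(−λt))`, `λ = K_F·E_F + K_R·E_R`.
The degenerate limit `E_R = 0, E_F > 0` returns the analytic limit
(`P → S_T`, `I → 0`) instead of dividing by zero, with a warning on the
steady-state path.

Dose sweeps default to a six-decade log-spaced window, `1e-3 … 1e3` in the
relevant input unit. This window is wide enough that observed-range
statistics (half-max thresholds, Hill fits of saturating curves) coincide
with their analytic definitions; several quantities — notably the Hill fit
of a composed non-Hill curve — depend measurably on the window, so it is
treated as a fixed package convention rather than a per-analysis knob.

## Promoters, gates and the comparator

Inducible promoters use a leaky Hill form
`vmax·(basal + (1−basal)·c^n/(c^n + K^n))`; `n = 1` recovers the
Michaelis–Menten form the gate models assume. The basal leak defaults to 2%
of vmax (measured OFF states are nonzero but no value is printed). Plasmid
copy number enters only as a vmax multiplier (LCP/MCP/HCP = 1/5/20,
configurable). Logic '0' is zero added inducer (leak only); logic '1' is
100×K, i.e. saturating induction without infinite inputs.

The two AND designs are: the MIN lattice,
`Out = soft_min(P_BAD(arab), P_lux(ahl))` with `soft_min(a,b) = ab/(a+b)`
(sandwiched between `min/2` and `min`), and the protein–protein gate,
`Out = LuxA·LuxB/K_AB`. Gate quality is the output dynamic range
`ODR = min over OFF corners of log10(I_ON/I_OFF)`. Under the symmetric
default promoters the two designs' ODR values are not ordered the way the
measured gates are; the measured ordering rests on asymmetries (copy
numbers, absolute expression scales) the naive model does not encode, so no
ordering is asserted — only the model-level properties (scale invariance,
corner definitions) are.

The comparator sweeps Arabinose through the forward branch at fixed AHL on
the reverse branch. Design `luxCDE-luxAB` takes `E_F = P_BAD(arab)²`
(dimer) and co-induced `E_R = P_lux(ahl)`; design `luxA-luxC` takes
`E_F = P_BAD(arab)·LuxB/K_AB` with LuxB constitutive, and models LuxD/LuxE
as non-limiting so `E_R` is set by LuxC alone — the simplest model
consistent with only luxA and luxC being inducible. The detection threshold
of a sweep is the input at half of the observed range, interpolated
linearly in log-input space. The fold-change constancy of the `luxA-luxC`
design holds exactly in the sub-threshold regime `E_F ≪ K_deff`, where
`I ∝ E_F` and the reverse drive cancels from the ON/OFF ratio
(`fold = 1/basal`); the tests construct that regime explicitly.

## Wild-type operon power law

With a single drive `x` for all five genes, `E_F = scale_F·x²` and
`E_R = scale_R·x`, giving the analytic local log–log slope
`1 + 1/(1 + γx)`, `γ = K_F·scale_F/(K_R·scale_R)`: strictly inside (1, 2),
tending to 2 at low drive and 1 at high drive. The package measures slopes
by central differences of log output against log input, and the
power-law-fit exponent over the mid-range window `x ∈ [0.1, 10]` is 1.50
under unit constants.

## Stress promoters and the crosstalk-compensating circuit

The delayed stress-promoter response is

    I(t) = X0 · rise(t) · decay(t) + c,
    rise(t)  = 0 for t < τ_D1, else 1 − e^(−(t−τ_D1)/τ_eff)
    decay(t) = [1 for t < τ_D2, else e^(−(t−τ_D2)/τ_1)] + β

Both exponentials are clamped to their pre-delay values; the printed model
clamps only the decay exponential, but zeroing the rise before its own
delay is required for `I(0) = c` and continuity, and is adopted as an
extension of the same convention. The β offset multiplies inside the decay
factor (i.e. the `t → ∞` limit is `X0·β + c`), following the printed
formula. Published parameter sets are bundled: katG/H2O2
(τ1=20, τ_eff=20, τ_D1=0, τ_D2=0, β=0.02, c=2000) and recA under NA
(60, 25, 60, 100, 0.1, c=9000) and H2O2 (30, 30, 0, 40, 0.25, c=9000).
The amplitudes X0 are not published; the package default is X0 = 1e5 for
the dimensional presets, placing the pulse peak roughly an order of
magnitude above the instrument floor `c` — the dynamic range lux stress
reporters display and the regime in which the described two-peak structure
is clearly visible. Promoter crosstalk (recA responding to both chemicals)
is modelled by summing the per-chemical pulses over a single shared
baseline (the instrument floor is not additive).

The crosstalk-compensating circuit is an incoherent type-1 feedforward
loop: katG (H2O2-specific) drives AHL production in a sender strain; in the
receiver, AHL induces TetR with delay, and TetR represses the luxAB branch
of a luxAB/luxCDE AND gate whose other branch is driven by recA. The AHL
proxy is the baseline-subtracted katG pulse normalized to unit peak (no
explicit LuxI synthesis/diffusion ODE — TetR ∝ AHL(t−τ_delay) is the stated
simplification), `τ_delay` defaults to 60 min (not published; chosen to
place the repression window over the early H2O2-driven response), and
repression follows `luxAB = 1/(1 + (TetR/0.2)²)`. Inside the loop the recA
drives use unit-amplitude, baseline-free pulse presets so the reverse
branch is order-unity and genuinely competes with the [0, 1]
repressor-gated forward branch; a configurable `er_scale` links pulse units
to enzyme units. Under these defaults the simulated output shows exactly
one prominent peak for either chemical alone and two for the mixture, with
a repression trough between them.

Peak counting uses `scipy.signal.find_peaks` with a prominence floor of 5%
of the trace's global range (endpoints never count; a flat trace has zero
peaks). In the H2O2-alone trace the post-repression recovery produces a
genuine but tiny interior maximum (~1% of the range); the prominence floor
is what makes "one peak per chemical" the robust readout, which is why the
prominence-filtered count is the documented statistic and the raw
strict-maximum count is exposed only via `min_prominence_frac=0`.

## Fitting

Hill and power-law fits operate on log-transformed outputs with uniform
weights (signals span decades and grids are log-spaced). The Hill model is
`basal + vmax·x^n/(x^n + K^n)`, reported in both the (K, n) form and the
aggregate form `x^n/(x^n + K̂)`, `K̂ = K^n`, which is how the published
dose-response fits are printed. Initialization: n = 1, K = geometric median
of the inputs, vmax = max output; up to five seeded perturbed restarts on
convergence failure, and failures are reported in the result, never
silently. Basal offsets are not fitted by default (`fit_basal=True` opts
in). Fits are deterministic given the data.

A consistency check composes the printed GFP Hill curve `x/(x+11)` with the
printed power-law exponent 1.45 and Hill-fits the composition over the
standard six-decade window: the result (n ≈ 1.42, K̂ ≈ 34) brackets the
printed bioluminescence fit (n = 1.5, K̂ = 30). The composition is not
exactly Hill-shaped, so this is a bracket, not an equality, and the fitted
values move slightly with the dose window.

## Synthetic data

The generator emulates plate-reader output: triplicate wells, a per-well
OD600 drawn uniformly in 0.4 ± 10%, multiplicative unit-mean lognormal
noise (CV configurable, default 10% — the published data report s.e.m. over
three experiments but no noise law), raw signals equal to model × noise ×
OD600, and OD normalization recovering the model value in expectation. Time
courses are simulated on a 1-min grid and down-sampled to the 15-min
instrument cadence over a 4-h default horizon (600 min for the stress
scenarios). OD variation is a per-well scalar, not a growth curve; there is
no toxicity, resource-competition or instrument-optics model. Noisy peak
counting is performed on the replicate-mean OD-normalized trace, matching
the average-of-three reporting convention of the measurements.

Because the generator is multiplicative-noise-only, passing tests show that
the analyses are correct and robust under the stated noise law and
replicate structure; they do not establish robustness to growth artefacts,
well-position effects or non-stationary baselines, which real plate data
contain.

## Problem sizes

Default analysis sizes are deliberately small: 200-point dose sweeps,
601-point (1-min) time grids over 10 h, 200-trial Monte-Carlo recovery and
100-trial robustness studies. These sizes give sub-second to few-second
runs while leaving the Monte-Carlo rates stable to within a couple of
percentage points across seeds.

## Known limitations

* No mechanistic FMN/FMNH₂ redox chemistry, ATP/NADPH bookkeeping, or
  cofactor depletion; the S/P/Y* abstraction is the whole chemistry.
* No host burden, resource competition, growth dynamics or spatial AHL
  diffusion; the sender:receiver ratio is not modelled.
* No stochastic chemical kinetics — noise enters only through the synthetic
  data generator.
* Measured gate ODR values and the measured GFP-vs-lux power-law exponent
  are figure-derived quantities; the package asserts the corresponding
  model-level properties instead of reproducing those numbers.
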