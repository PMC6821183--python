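# Scenario config for `luxcircuit run`: crosstalk-compensating circuit,
# all four dose combinations, traces + peak summary written to outdir.
scenario: iffl
seed: 1
outdir: scratch_iffl_run
iffl:
  tau_delay: 60.0
  t_max: 600.0
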