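# Example run configuration for `markovcea run` / `tornado` / `validate`.
# Every key is optional; unknown keys are rejected.
strategies: [PD, PDE, PGD, PDG, PGDE, PDEG]
cohort:
  start_age: 40.0
  life_expectancy: 73.6
  cycle_length: 0.5
economy:
  gdp_per_capita_usd: 3756
  exchange_rate: 23486
discount_rate: 0.03
half_cycle: false
sensitivity:
  fraction: 0.20
  # comparisons default to the four glucosamine add-on scenarios
output_dir: results
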