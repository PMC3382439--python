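# Example guided-evolution experiment for `evoguide schedule`.
# Pre-evolve founders in OR for a fixed 60 epochs, then evolve in XOR until
# the population-mean fitness reaches 0.75 (or the epoch budget runs out).

population_size: 128
replicates: 2
master_seed: 0
delay: 500
threshold: 0.75

# Any CellParams / MutationConfig / HGTConfig field can be overridden:
# cell_params:
#   metabolism_gain: 4.0
# mutation:
#   p_rate_perturbation: 0.3
hgt:
  enabled: true
  p_transfer: 0.05

schedule:
  name: OR->XOR
  stages:
    - gate: OR
      budget_epochs: 60
      threshold: null
      fixed_epochs: 60
      source: founders
    - gate: XOR
      budget_epochs: 500
      threshold: 0.75
      source: continue
      hgt: false
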