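# Desk-scale perceptography campaign.  Omitted keys take the documented
# defaults; unknown keys are rejected.
master_seed: 1
n_seeds: 5
pool_size: 100          # per seed; full-scale runs use 400-1000
min_presentations: 5
iteration_budget: 5
dilution_fraction: 0.5  # fraction of presentations from the non-optimized pool
intensity_mw: 3.0       # stimulation optical power (operating range 1-11)
children_per_parent: 4  # mutated children per surviving image, within [2, 6]
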