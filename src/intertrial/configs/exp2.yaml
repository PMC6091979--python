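# Dimension discrimination: a target on every trial; 3 sections
# (75/50/25% color targets) x 10 blocks x 40 trials.
experiment: exp2_dimension_discrimination
spec: LATER+nd/rdf=s0_decay/tdd=rate_decay
outer_params: {rdf_alpha: 0.8, rdf_beta0: 2.0, tdd_alpha: 0.9, tdd_delta: 0.1}
n_participants: 12
lapse_rate: 0.025
seed: 22
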