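# Blocked detection: 3 sections (75/50/25% target-present) x 10 blocks x 40
# trials, color/orientation targets in alternating blocks.
experiment: exp1_detection_blocked
spec: LATER+nd/rdf=s0_decay/tdd=no_update
outer_params: {rdf_alpha: 0.8, rdf_beta0: 2.0}
n_participants: 12
lapse_rate: 0.015
seed: 11
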