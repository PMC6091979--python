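# Mixed detection: 18 De Bruijn-balanced 65-trial blocks, 50/50
# present/absent, color and orientation targets interleaved.
experiment: exp3_detection_mixed
spec: LATER+nd/rdf=s0_decay/tdd=rate_weighted
outer_params: {rdf_alpha: 0.8, rdf_beta0: 2.0, tdd_alpha: 0.9, tdd_delta: 0.1}
n_participants: 12
lapse_rate: 0.033
seed: 33
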