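# Canonical versioned test corpus: generator configuration + seed.
# Regenerating with this config is byte-reproducible.
n_patients: 500
prevalence: 0.051
p_definite_given_asthma: 0.6
notes_per_patient: [2, 5]
date_range: ["2000-01-01", "2009-12-31"]
p_negation_distractor: 0.3
p_family_distractor: 0.3
p_exclusion: 0.02
p_minor_criterion: 0.5
p_benign_observation: 0.3
template_noise: 0.3
seed: 12345
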