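# PlexA RNAi in pSc neurons: supernumerary branches, doubled varicosities,
# Published cohort statistics (mean +/- SEM at the published n); the
# presence/routing rates encode the genotype's skeletal-loss and branch
# misrouting phenotypes against the 16-branch wildtype template.
name = plexa_rnai
n_animals = 37
target_branch_mean = 31.0
target_branch_sem = 0.8
target_total_len_mean = 1219
target_total_len_sem = 32
target_varicosity_mean = 68.2
target_varicosity_sem = 13
guidance_error_rate = 0.14
routing_error_rate = 0.1375
skeleton_presence_scale = 1.0
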