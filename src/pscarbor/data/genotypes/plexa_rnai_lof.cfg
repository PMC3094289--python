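# PlexA RNAi combined with the LOF heterozygote: strong guidance and routing errors.
# Published cohort statistics (mean +/- SEM at the published n); the
# presence/routing rates encode the genotype's skeletal-loss and branch
# misrouting phenotypes against the 16-branch wildtype template.
name = plexa_rnai_lof
n_animals = 10
target_branch_mean = 31.0
target_branch_sem = 2.0
target_total_len_mean = 1305
target_total_len_sem = 49
target_varicosity_mean = 79.8
target_varicosity_sem = 14
guidance_error_rate = 0.56
routing_error_rate = 0.25
skeleton_presence_scale = 1.0
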