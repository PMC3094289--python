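# PlexB loss-of-function heterozygote: wildtype-like arbor.
# Published cohort statistics (mean +/- SEM at the published n); the
# presence/routing rates encode the genotype's skeletal-loss and branch
# misrouting phenotypes against the 16-branch wildtype template.
name = plexb_lof_het
n_animals = 21
target_branch_mean = 22.7
target_branch_sem = 0.6
target_total_len_mean = 902
target_total_len_sem = 23
target_varicosity_mean = 36.1
target_varicosity_sem = 13
guidance_error_rate = 0.19
routing_error_rate = 0.0
skeleton_presence_scale = 1.0
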