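# PlexA loss-of-function heterozygote: modest branch increase, no guidance defect.
# Published cohort statistics (mean +/- SEM at the published n); the
# presence/routing rates encode the genotype's skeletal-loss and branch
# misrouting phenotypes against the 16-branch wildtype template.
name = plexa_lof_het
n_animals = 15
target_branch_mean = 26.5
target_branch_sem = 0.7
target_total_len_mean = 990
target_total_len_sem = 131
target_varicosity_mean = 35.5
target_varicosity_sem = 5
guidance_error_rate = 0.06
routing_error_rate = 0.04
skeleton_presence_scale = 1.0
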