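# w- wildtype control: no guidance errors; stereotyped 16-branch skeleton.
# Published cohort statistics (mean +/- SEM at the published n); the
# presence/routing rates encode the genotype's skeletal-loss and branch
# misrouting phenotypes against the 16-branch wildtype template.
name = wildtype
n_animals = 21
target_branch_mean = 22.5
target_branch_sem = 0.3
target_total_len_mean = 906
target_total_len_sem = 19
target_varicosity_mean = 28.3
target_varicosity_sem = 4
guidance_error_rate = 0.0
routing_error_rate = 0.0
skeleton_presence_scale = 1.0
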