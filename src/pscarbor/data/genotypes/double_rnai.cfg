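# Simultaneous PlexA+PlexB RNAi: extra branches with near-control arbor size.
# Published cohort statistics (mean +/- SEM at the published n); the
# presence/routing rates encode the genotype's skeletal-loss and branch
# misrouting phenotypes against the 16-branch wildtype template.
name = double_rnai
n_animals = 16
target_branch_mean = 30.9
target_branch_sem = 2.0
target_total_len_mean = 1161
target_total_len_sem = 54
target_varicosity_mean = 40.9
target_varicosity_sem = 10
guidance_error_rate = 0.0
routing_error_rate = 0.14
skeleton_presence_scale = 1.0
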