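# 455-Gal4 driver-alone control (scutellar driver insertion).
# Published cohort statistics (mean +/- SEM at the published n); the
# presence/routing rates encode the genotype's skeletal-loss and branch
# misrouting phenotypes against the 16-branch wildtype template.
name = driver_control
n_animals = 20
target_branch_mean = 24.4
target_branch_sem = 0.7
target_total_len_mean = 1045
target_total_len_sem = 31
target_varicosity_mean = 35.7
target_varicosity_sem = 7
guidance_error_rate = 0.15
routing_error_rate = 0.0
skeleton_presence_scale = 1.0
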