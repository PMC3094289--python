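# PlexB RNAi in pSc neurons: ~3.3 skeletal branches lost, smaller arbor.
# Published cohort statistics (mean +/- SEM at the published n); the
# presence/routing rates encode the genotype's skeletal-loss and branch
# misrouting phenotypes against the 16-branch wildtype template.
name = plexb_rnai
n_animals = 42
target_branch_mean = 21.5
target_branch_sem = 0.7
target_total_len_mean = 918
target_total_len_sem = 28
target_varicosity_mean = 37.4
target_varicosity_sem = 8
guidance_error_rate = 0.05
routing_error_rate = 0.0
skeleton_presence_scale = 0.843
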