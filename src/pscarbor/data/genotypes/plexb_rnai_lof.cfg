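# PlexB RNAi combined with the LOF heterozygote: phenocopies the RNAi alone.
# Published cohort statistics (mean +/- SEM at the published n); the
# presence/routing rates encode the genotype's skeletal-loss and branch
# misrouting phenotypes against the 16-branch wildtype template.
name = plexb_rnai_lof
n_animals = 20
target_branch_mean = 21.9
target_branch_sem = 0.9
target_total_len_mean = 897
target_total_len_sem = 30
target_varicosity_mean = 34.0
target_varicosity_sem = 10
guidance_error_rate = 0.15
routing_error_rate = 0.0
skeleton_presence_scale = 0.843
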