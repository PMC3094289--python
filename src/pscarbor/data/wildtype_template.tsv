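# Wildtype posterior-scutellar (pSc) skeleton template: 16 core branches.
# Branch mean lengths span 13-151 um; per-branch SDs default to 20% CV
# (the published figure marks per-branch variability but prints no numbers).
# Geometry is laid out so that no two non-adjacent branches approach within
# ~4 um in projection, keeping rendered arbors traceable.
# columns: id parent_id attach_fraction dir_x dir_y mean_length sd_length presence_prob
b01	-	0.00	0.550	0.835	151.0	30.2	1.00
b02	b01	0.15	1.000	0.000	70.0	14.0	0.98
b03	b01	0.30	-0.500	0.866	62.0	12.4	0.98
b04	b01	0.45	0.970	-0.243	55.0	11.0	0.98
b05	b01	0.62	0.966	0.259	49.0	9.8	0.98
b06	b01	0.78	-0.600	0.800	79.0	15.8	0.98
b07	b01	0.92	0.966	0.259	39.0	7.8	0.98
b16	b01	0.95	-0.087	0.996	44.0	8.8	0.98
b08	b02	0.50	0.320	-0.947	35.0	7.0	0.98
b09	b02	0.85	0.800	0.600	31.0	6.2	0.98
b10	b03	0.78	0.139	0.990	28.0	5.6	0.98
b11	b04	0.55	0.450	0.893	25.0	5.0	0.98
b12	b05	0.40	0.259	0.966	22.0	4.4	0.98
b13	b06	0.60	-0.970	0.240	19.0	3.8	0.98
b14	b07	0.65	0.259	0.966	16.0	3.2	0.98
b15	b06	0.85	-0.940	0.342	13.0	2.6	0.98
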