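sample	reads_r1	truncated_r1	truncated_r1_pct	unique_r1	unique_r1_pct	multi_r1	multi_r1_pct	unmapped_r1	unmapped_r1_pct	reads_r2	truncated_r2	truncated_r2_pct	unique_r2	unique_r2_pct	multi_r2	multi_r2_pct	unmapped_r2	unmapped_r2_pct	pairs_in	paired	paired_pct	ditags_paired	valid	valid_pct	circularised	circularised_pct	dangling_end	dangling_end_pct	internal	internal_pct	religation	religation_pct	contiguous	contiguous_pct	wrong_size	wrong_size_pct	not_at_cut_site	not_at_cut_site_pct	wrong_enzyme	wrong_enzyme_pct	valid_cis	valid_trans	unique_ditags	unique_pct	cis	trans	trans_pct	cis_trans_ratio
golden	626	20	3.19489	626	100	0	0	0	0	626	40	6.38978	626	100	0	0	0	0	626	626	100	626	294	46.9649	61	9.74441	79	12.6198	57	9.10543	50	7.98722	44	7.02875	41	6.54952	0	0	0	0	229	65	194	65.9864	151	43	22.1649	0.284768
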