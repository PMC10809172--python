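score	cpg	chr	pos	gene	beta_m1	se_m1	p_m1	beta_m2	se_m2	p_m2	i2_m1	i2_m2	pct_change_printed
MMDS	cg05575921	5	373378	AHRR	0.0688	0.0110	3.70e-10	0.0800	0.0212	1.66e-04	0.20	0	-16.2357
HPDI	cg23900905	8	82641291		0.0774	0.0136	1.37e-08	0.0771	0.0219	4.38e-04	0	0	0.3983
MMDS	cg13518625	8	29522838		0.0655	0.0118	2.62e-08	0.0685	0.0235	3.61e-03	0.46	0	-4.5291
HPDI	cg02650017	17	47301614	PHOSPHO1	0.0683	0.0121	1.75e-08	0.0646	0.0219	3.19e-03	0.14	0	5.3190
MMDS	cg18181703	17	76354621	SOCS3	0.0778	0.0116	2.09e-11	0.0824	0.0245	7.65e-04	0.29	0	-5.8260
MMDS	cg00711496	19	50191497	PRMT1	0.0710	0.0132	9.24e-08	0.0711	0.0248	4.11e-03	0	0	0.4841
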