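score	cpg	chr	pos	gene	beta	se	p	i2
DASH	cg05399785	1	3564031	WDR8	-0.059	0.011	4.62e-08	0
DASH	cg12728588	1	36025489	NCDN	-0.057	0.011	8.71e-08	0
DASH	cg03084350	3	38065265	PLCD1	-0.053	0.009	1.60e-09	0.557
DASH	cg02107842	5	66255772	MAST4	-0.044	0.008	1.59e-08	0
MMDS	cg05575921	5	373378	AHRR	0.069	0.011	3.70e-10	0.089
HPDI	cg27395200	6	32942710	BRD2	-0.054	0.010	1.14e-08	0.003
DASH	cg08774868	7	80399952	SEMA3C	-0.063	0.011	2.92e-09	0.458
DASH	cg13518625	8	29522838		0.066	0.011	1.75e-09	0.510
MMDS	cg13518625	8	29522838		0.066	0.012	3.13e-08	0.488
HPDI	cg23900905	8	82641291		0.077	0.014	1.37e-08	0
DASH	cg23761815	10	73083123	SLC29A3	-0.054	0.009	1.03e-09	0.265
DASH	cg00574958	11	68607622	CPT1A	0.068	0.011	1.24e-09	0.022
HPDI	cg02079413	11	2986505	SNORA54	-0.065	0.012	5.03e-08	0.478
DASH	cg01678580	16	4674018	MGRN1	-0.052	0.009	3.61e-08	0
DASH	cg03819286	16	4673974	MGRN1	-0.047	0.008	2.20e-09	0.309
HPDI	cg03819286	16	4673974	MGRN1	-0.052	0.008	5.00e-10	0
HPDI	cg02650017	17	47301614	PHOSPHO1	0.068	0.012	1.75e-08	0.141
MMDS	cg18181703	17	76354621	SOCS3	0.078	0.012	4.08e-11	0.426
DASH	cg20761853	17	76850198	TIMP2	-0.056	0.010	6.81e-09	0.072
MMDS	cg00711496	19	50191497	PRMT1	0.071	0.013	8.28e-08	0
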