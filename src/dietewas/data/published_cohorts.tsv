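sample	n	n_female	age_mean	age_sd	bmi_mean	bmi_sd	mmds_mean	dash_mean	hpdi_mean
WHI	1736	1736	64.2	7.05	29.8	6.02	12.0	24.3	54.7
FOS	1843	1045	66.4	8.87	28.2	5.37	12.1	24.4	52.1
REGICOR-450K	573	285	57.9	11.44	27.2	3.93	11.8	24.5	57.4
REGICOR-EPIC	269	139	56.0	7.03	28.3	5.87	11.9	23.9	57.6
AIRWAVE	853	366	41.1	9.37	27.1	4.41	11.8	23.9	55.7
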