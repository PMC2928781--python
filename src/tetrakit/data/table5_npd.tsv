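interval	genotype	tetrads_N	npd_obs	npd_exp	ratio	p_value	interference
TRP5-CYH2	wild-type	572	9	33.4	0.269	<0.0001	YES
TRP5-CYH2	msh4-R676W	704	3	17.0	0.176	0.0001	YES
CEN8-THR1	wild-type	572	2	12.5	0.16	0.0007	YES
CEN8-THR1	msh4-R676W	704	2	8.15	0.245	0.0186	YES
THR1-CUP1	wild-type	572	1	17.56	0.056	<0.0001	YES
THR1-CUP1	msh4-R676W	704	5	11.63	0.430	0.030	YES
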