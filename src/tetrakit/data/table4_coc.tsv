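interval_pair	genotype	tetrads_N	dco_obs	dco_exp	coc	p_value	interference
HIS4-LEU2-CEN3	wild-type	572	5	17.5	0.286	0.004	YES
HIS4-LEU2-CEN3	msh4-R676W	704	14	16.2	0.864	0.667	NO
LEU2-CEN3-MAT	wild-type	572	16	19.7	0.813	0.465	NO
LEU2-CEN3-MAT	msh4-R676W	704	31	24.8	1.251	0.242	NO
TRP5-CYH2-MET13	wild-type	572	57	64.4	0.886	0.363	NO
TRP5-CYH2-MET13	msh4-R676W	704	27	38.7	0.698	0.064	NO
CYH2-MET13-LYS5	wild-type	572	20	38.9	0.514	0.002	YES
CYH2-MET13-LYS5	msh4-R676W	704	12	22.9	0.523	0.027	YES
CEN8-THR1-CUP1	wild-type	572	67	107.2	0.625	<0.0001	YES
CEN8-THR1-CUP1	msh4-R676W	704	43	71	0.606	0.0005	YES
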