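allele	class	domain	n_tetrads	spore_viability_pct	total_cM
wild-type			199	97.0	96.1
msh4Δ			557	35.9	39.2
msh5Δ			3990	36	37
msh4-E111A	2	II	117	93.4	80.5
msh4-N126A	1	II	109	91.7	81.1
msh4-D139A	2	II	100	31	38.6
msh4-Y143A	2	II	118	76.1	41.5
msh4-F194A	1	II	120	56.7	44.1
msh4-N195A	2	II	120	95.4	87.6
msh4-D210A	1	II	120	96.9	74.2
msh4-D268A	1	II	120	95	70.7
msh4-E276A	2	II	180	88.9	53.2
msh4-E324A	2	III	119	95.2	101.6
msh4-E328A	2	III	119	95.4	83.9
msh4-N409A	2	III	120	95	95.4
msh4-E425A	2	III	119	92.6	89
msh4-D453A	1	IV	120	93.8	88.2
msh4-R456A	1	IV	100	61	40.5
msh4-E461A	2	IV	118	92.4	94.2
msh4-Y485A	4	IV	119	94.7	76.7
msh4-F491A	1	IV	100	91	47.6
msh4-L493A	4	IV	100	75	43.5
msh4-I495A	4	IV	120	91.7	79.5
msh4-N532A	1	IV	118	89.4	64.5
msh4-R534A	2	IV	119	91.8	74.3
msh4-I542A	4	IV	99	85	59.1
msh4-L553A	4	IV	119	95	84.9
msh4-G639A	4	V	99	30	42.6
msh4-R676W	4	V	120	89.6	55.6
msh4-E732A	2	V	99	93	82.6
msh4-H764A	2	V	119	94.5	81.6
msh4-D772A	2	V	120	91.3	67.4
msh5-E45A	3	II	120	91.5	83.6
msh5-D76A	1	II	100	88	53.9
msh5-E135A	3	II	179	93.9	89.5
msh5-D147A	3	II	120	96.7	87.7
msh5-F161A	1	II	119	90.3	74.8
msh5-N182A	1	II	120	91	83.2
msh5-D250A	1	II	99	91	60
msh5-W298A	3	III	120	40.2	30.6
msh5-S416A	3	III	200	90.9	60
msh5-T423A	3	III	120	95.2	78.3
msh5-D433A	1	IV	120	47.3	37
msh5-R436A	1	IV	119	50.2	37.6
msh5-Y480A	3	IV	100	67	37.8
msh5-Y486A	1	IV	120	93.8	62.9
msh5-V488A	4	IV	119	39.7	39.6
msh5-I490A	4	IV	120	96	80.1
msh5-E495A	3	IV	120	92.3	73.9
msh5-D527A	1	IV	116	30.2	34.3
msh5-D532A	3	IV	100	64.5	38.7
msh5-I537A	4	IV	119	87.8	66.1
msh5-D539A	3	IV	180	90.4	63.9
msh5-L548A	4	IV	120	50.2	36.1
msh5-G648A	4	V	117	33.3	34
msh5-Y661A	3	V	120	45.8	33.6
msh5-D680A	3	V	100	75	38.6
msh5-R685W	4	V	120	36	35.2
msh5-R837A	3	V	120	93.8	78.7
msh5-F876A	3	V	100	94.3	83.6
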