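marker	chromosome	position_cM	is_centromere_linked	is_mating_type
HIS4	III	0.0	0	0
LEU2	III	13.8	0	0
CEN3	III	19.9	1	0
MAT	III	34.8	0	1
TRP5	VII	0.0	0	0
CYH2	VII	36.0	0	0
MET13	VII	45.3	0	0
LYS5	VII	66.4	0	0
CEN8	VIII	0.0	1	0
THR1	VIII	21.5	0	0
CUP1	VIII	46.2	0	0
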