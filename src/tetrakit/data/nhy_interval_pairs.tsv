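chromosome	markerA	markerB	markerC
III	HIS4	LEU2	CEN3
III	LEU2	CEN3	MAT
VII	TRP5	CYH2	MET13
VII	CYH2	MET13	LYS5
VIII	CEN8	THR1	CUP1
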