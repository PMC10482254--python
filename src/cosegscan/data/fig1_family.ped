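FAM1	I_1	0	0	1	2	1
FAM1	I_2	0	0	2	1	1
FAM1	II_1	I_1	I_2	1	2	1
FAM1	II_2	0	0	2	1	1
FAM1	III_1	II_1	II_2	1	2	1
FAM1	III_2	II_1	II_2	2	1	1
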