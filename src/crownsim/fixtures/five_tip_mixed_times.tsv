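label	birth_time	death_time	extant
L	0	4	0
A	4	12	1
M	4	7	0
B	7	12	1
C	7	12	1
R	0	6	0
D	6	10	0
F	6	8	0
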