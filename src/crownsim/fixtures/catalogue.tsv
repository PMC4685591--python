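name	present_time	n_tips	n_extant	crown_node	crown_time	crown_fraction
two_tip_extant	10	2	2	origin	0	0
one_side_extinct	10	4	2	n2	7	0.7
five_tip_mixed	12	5	3	L	4	0.3333333333333333
single_survivor	10	2	1
crown_at_origin	10	4	3	origin	0	0
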