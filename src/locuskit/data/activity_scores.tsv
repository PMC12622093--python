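# CYP2D6 star-allele activity values, CPIC-derived; version=cpic-2023-derived
# phenotype bins: 0 -> PM; (0, 1] -> IM; (1, 2.25] -> NM; > 2.25 -> UM
star	activity
*1	1.0
*2	1.0
*3	0.0
*4	0.0
*5	0.0
*6	0.0
*9	0.5
*10	0.25
*17	0.5
*29	0.5
*41	0.5
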