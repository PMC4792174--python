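# Elemental-composition deltas for common search modifications.
# Negative values remove atoms (e.g. deamidation: -NH +O on the amide).
# name	C	H	N	O	S	P
carbamidomethyl	2	3	1	1	0	0
oxidation	0	0	0	1	0	0
acetyl	2	2	0	1	0	0
phospho	0	1	0	3	0	1
gg	4	6	2	2	0	0
deamidation	0	-1	-1	1	0	0
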