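group	min_aa	max_aa	NHLP	N11P	HETP	DUF37	OTHER	novel
I	45	164	1	2	1	1	15	1
II	39	152	12	7	10	0	58	11
III	29	129	26	6	0	2	40	21
IV	31	151	16	29	0	1	15	4
V	28	151	11	10	0	0	16	9
VI	82	84	0	0	0	2	0	0
VII	50	116	0	1	0	0	6	0
UNCLASSIFIED	159	159	0	0	2	0	0	0
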