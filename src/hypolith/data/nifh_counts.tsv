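# Published nifH OTU counts per location used as the worked-example input.
otu	taklimakan	devon_island	tibetan	mcmurdo	order
1	0	0	23	0	Rhizobiales
2	0	0	12	0	Burkholderiales
3	0	0	7	0	Rhodospirillales
4	6	0	0	0	Rhodospirillales
5	0	0	3	0	Unknown
6	2	0	0	1	Rhizobiales
7	0	0	0	3	Burkholderiales
8	2	0	0	0	Rhizobiales
9	0	0	1	0	Rhodospirillales
10	0	0	1	0	Rhodospirillales
11	1	0	0	0	Rhizobiales
12	1	0	0	0	Pseudomonadales
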