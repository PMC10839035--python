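Gene_Name	Wild_Type	Position	Frequency
PCFS1	Gly	5	1
PAPS2	Arg	307	2
PAPS3	Trp	54	2
PAPS3	Glu	198	2
PAPS3	Leu	209	1
PAPS3	Tyr	492	13
PABN3	Glu	33	1
CLPS5	Trp	421	1
CLPS5	Gln	259	1
CLPS5	Arg	209	1
CLPS5	Arg	98	21
CLPS5	Gln	97	547
CLPS5	Gln	95	1
CLPS5	Arg	18	18
PCFS5	Tyr	83	9
PCFS5	Ser	95	1
PCFS5	Leu	99	1
PCFS5	Arg	281	1
PCFS5	Gln	284	3
FIPS5	Arg	1186	28
CSTF50	Arg	212	1
PQT3	Gln	453	1
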