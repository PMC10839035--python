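Gene_Name	Wild_Type	Position	SNP	Frequency
PCFS1	Asp	364	Ala	1077
PCFS1	Leu	217	Ser	1042
CSTF64	Phe	363	Tyr	1066
PAPS3	Ile	180	Ser	1100
PAPS3	Thr	297	Asn	1013
PAPS3	Leu	312	Arg	1098
FIPS3	Tyr	273	Asp	1111
ESP4	Asp	1398	Glu	1096
ESP4	Met	791	Lys	1096
ESP4	Gly	585	Val	1062
CPSF100	Ile	441	Val	1066
PCFS5	Val	115	Gly	1009
PCFS5	Asn	215	Ser	1013
PABN1	Lys	89	Glu	1065
PQT3	Ser	715	Pro	1050
Mpe1	Pro	809	Ser	1048
Mpe1	Thr	693	Pro	1044
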