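gene_name	sequence_change	Frequency
CFIS1	p.Ser14_Asp15fs/c.42_43insC	6
CFIS1	p.Ser14_Asp15fs/c.40_41insAT	4
CLPS5	p.Tyr401fs/c.1202_1203delAT	5
CLPS5	p.Ile399fs/c.1195delA	12
CLPS5	p.Arg398_Ile399fs/c.1194_1195ins	1
CLPS5	p.Val322_Lys323fs/c.966_967insT	1
CLPS5	p.Gly238fs/c.713delG	12
CLPS5	p.Val235fs/c.705_708delTCGT	1
CLPS5	p.Lys182_Ala183fs/c.545_546insA	14
CLPS5	p.Phe147_Val148fs/c.441_442insAA	4
CLPS5	p.Lys140fs/c.420_432delAGATGGTTG	1
CLPS5	p.Ser79fs/c.235delT	1
CLPS5	p.Ala36fs/c.106delG	1
CLPS5	p.Glu16_Leu17fs/c.46_47insCG	10
CLPS5	p.Gly3fs/c.9delT	3
CSTF50	p.Ser120fs/c.358delT	2
CSTF50	p.Val249fs/c.746_753delTAAACACA	1
ESP4	p.Gly585fs/c.1754_1755delGG	2
ESP4	p.Asp584fs/c.1751delA	3
FIPS3	c.2993_2994insA	807
PABN1	p.Glu124fs/c.371delA	1
PAPS2	p.Asn697_Glu698fs/c.2090_2091ins	6
PAPS3	p.Asp36fs/c.108delT	2
PAPS3	p.Ile76_Leu77fs/c.226_227insA	3
PAPS3	p.Asp108_Phe109fs/c.324_325insT	2
PAPS3	p.Asn221_Gly222fs/c.661_662insA	3
PAPS3	p.Phe430fs/c.1290delC	1
PAPS3	p.Leu441fs/c.1321_1325delCTTGT	3
PAPS3	p.Lys460fs/c.1378delA	20
PAPS4	p.His739fs/c.2217_2218delTG	2
PCFS1	p.Thr168fs/c.504_505delTC	1
PCFS1	p.Ser142fs/c.424delT	9
PCFS1	p.Gly118_Asn119fs/c.352_353insA	2
PCFS1	p.Ser80fs/c.240_241delTC	1
PCFS2	p.Thr876fs/c.2626delA	1
PCFS2	p.His866fs/c.2597delA	9
PCFS2	p.Ser141_Cys142fs/c.421_422insT	1
PCFS5	p.Asp89fs/c.267_268delTG	15
PCFS5	p.Ala98_Leu99fs/c.294_295insT	3
PCFS5	p.Asn118fs/c.354delC	5
PCFS5	p.Asn175fs/c.525_526delCA	129
PCFS5	p.Met176fs/c.528_534delGGTTTCA	246
PCFS5	p.Asn226fs/c.678delT	4
PCFS5	p.Ile238fs/c.713delT	7
PCFS5	p.Gln331fs/c.993_994delAC	3
PCFS5	p.Val334_Pro335fs/c.1000_1001ins	8
PCFS5	p.Ala344fs/c.1031delC	6
PCFS5	p.Leu345fs/c.1033delT	5
PQT3	p.Trp418_Ala419fs/c.1252_1253ins	430
PQT3	p.Trp418_Ala419fs/c.1253_1254ins	311
PQT3	p.Glu664fs/c.1990_1991delGA	1
PQT3	p.Arg665fs/c.1995delT	1
PAPS3	p.Cys507fs/c.1519_1528delTGTTAGG	10
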