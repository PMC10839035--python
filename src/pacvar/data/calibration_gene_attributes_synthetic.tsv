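gene_id	protein_length	missense_count	pi_group	nonstop_fraction	relative_expression
PCFS1	464	109	intermediate	0.80	5.0
PCFS5	404	123	diversifying	0.75	4.0
CLPS5	445	80	diversifying	0.60	1.2
CSTF50	442	40	diversifying	NA	8.0
PAPS3	560	70	diversifying	NA	30.0
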