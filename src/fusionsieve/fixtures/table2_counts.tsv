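exclusivity_class	category	count	printed_pct
LM_unique	intrachromosomal	614	37.9
LM_unique	interchromosomal	1003	62.1
LM_unique	coding	1245	76.9
LM_unique	noncoding	372	23.1
LM_unique	in_frame	136	8.5
LM_unique	out_of_frame	1481	91.5
pCRC_unique	intrachromosomal	838	56.1
pCRC_unique	interchromosomal	658	43.9
pCRC_unique	coding	1137	76
pCRC_unique	noncoding	359	24
pCRC_unique	in_frame	47	3.1
pCRC_unique	out_of_frame	1449	96.9
common	intrachromosomal	74	79.5
common	interchromosomal	19	20.5
common	coding	73	78.5
common	noncoding	20	21.5
common	in_frame	5	5.3
common	out_of_frame	88	94.7
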