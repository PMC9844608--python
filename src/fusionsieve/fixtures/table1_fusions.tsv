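gene5	tx5	chrom5	pos5	gene3	tx3	chrom3	pos3	strand5	strand3	inframe_label	functional_domain	fusion_type	samples	read_counts	selected
EVI5	ENST00000370331	chr1	93029199	GFI1	ENST00000427103	chr1	92944310	-	-	1 > 0	Zinc finger C2H2-type	Intrachromosomal	SRR975592;SRR3827632;SRR10160732	7;6;6	1
LNX1	ENST00000306888	chr4	54342920	FIP1L1	ENST00000358575	chr4	54324820	-	+	0 > 1	C3HC4 RING-type	Intrachromosomal	SRR975587;SRR10160731	5;5	0
PRKAA1	ENST00000397128	chr5	40771821	PTPN22	ENST00000528414	chr1	114372329	-	-	2 > 2	Serine/threonine-protein kinase	Interchromosomal	SRR975589;SRR3827633	5;5	0
MAP3K5	ENST00000359015	chr6	136901439	MAP7	ENST00000354570	chr6	136742937	-	-	2 > 2	Serine/threonine-protein kinase	Intrachromosomal	SRR975587;SRR10160731	6;5	0
DCAF11	ENST00000559115	chr14	24592286	PSME1	ENST00000382708	chr14	24606194	+	+	2 > 0	Proteasome activator pa28	Intrachromosomal	SRR975593;SRR975594;SRR10160731	7;5;6	1
CLRN3	ENST00000368671	chr10	129690820	DOCK1	ENST00000280333	chr10	128768966	-	+	2 > 2	DNA-binding domain	Intrachromosomal	SRR975587;SRR3827632	8;5	0
THBS1	ENST00000260356	chr15	39885003	NFIB	ENST00000380959	chr9	14179779	+	-	0 > 2	Zinc finger, C2H2-like	Interchromosomal	SRR10160731;SRR975588	6;5	0
LIME1	ENST00000309546	chr20	62369852	SLC2A4RG	ENST00000266077	chr20	62371730	+	+	2 > 0	Zinc finger, C2H2-like	Intrachromosomal	SRR975588;SRR975595	9;6	0
LARS2	ENST00000265537	chr3	45565600	LIMD1	ENST00000273317	chr3	45677642	+	+	0 > 2	Zinc finger, LIM-type	Intrachromosomal	SRR3827632;SRR3827633	5;5	0
ADAP1	ENST00000265846	chr7	959605	NOC4L	ENST00000330579	chr12	132635526	-	+	2 > 2	Arf GTPase activating protein /CCAATbinding factor	Interchromosomal	SRR5131510;SRR10160731;SRR987590;SRR975592;SRR975594;SRR10160732;SRR3827632	6;8;6;5;7;6;6	1
SPPL2A	ENST00000261854	chr15	51012137	TRPM7	ENST00000560955	chr15	50955243	-	-	1 > 0	MHCK/EF2 kinase	Intrachromosomal	SRR975593;SRR10160731	5;5	0
APLF	ENST00000303795	chr2	68753374	SPTLC1	ENST00000262554	chr9	94871116	+	-	2 > 0	SMAD/FHA domain	Interchromosomal	SRR4457128;SRR3827632;SRR10160732	5;5;5	1
COL4A1	ENST00000375820	chr13	110817209	CAMK2D	ENST00000296402	chr4	114582928	-	-	2 > 2	calmodulin-dependent protein kinase II	Interchromosomal	SRR975587;SRR975594	6;5	0
RNF43	ENST00000407977	chr17	56494378	SUPT4H1	ENST00000225504	chr17	56428869	-	-	-	Transcription elongation factor (Spt4)	Intrachromosomal	SRR975588;SRR987590;SRR975592;SRR975597;SRR4457128;SRR3827632;SRR975593;SRR10160731	6;6;6;5;8;6;5;5	1
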