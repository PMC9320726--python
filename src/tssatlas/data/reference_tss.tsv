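gene	strain	method	promoter	replicon	position	strand	utr_length	minus35	minus10	spacer	comment
dcmA	M. extorquens DM4	dRNA-seq	P_A	chromosome	2562877	+	173	TTGACA	TATAGA	16	this study; TSS position 2562877 (plus)
dcmA	M. extorquens DM4	nuclease S1	P_A				175	TTGACA	TATAGA	16	TSS identified from cloned DNA
dcmA	Methylophilus sp. DM11	primer extension	P_A				122	TTGACA	TATAGT	17	
dcmR	M. extorquens DM4	dRNA-seq	P_R1	chromosome	2562332	-	66	TTGCGC	TAACTA	17	this study; TSS position 2562332 (minus)
dcmR	M. extorquens DM4	nuclease S1	P_R1				62	TTGCGC	TAACTA	17	TSS identified from cloned DNA
dcmR	M. extorquens DM4	dRNA-seq	P_R2	chromosome	2562423	-	157	TTTACT	TTTACT	16	this study; TSS position 2562423 (minus)
dcmR	M. extorquens DM4	nuclease S1	P_R2				157	TTTACT	TTTACT	16	TSS identified from cloned DNA
glyA	M. extorquens DM4	dRNA-seq		chromosome	3888433	-	75	TTGGCC	ACGAAT	18	this study; TSS position 3888433 (minus)
glyA	M. extorquens AM1	primer extension					84	ATCACC	TGCCGC	16	other TSS with 63 and 38 nt 5'UTR reported
lspA	M. extorquens DM4	dRNA-seq	P_ileS	chromosome	3023525	+	150	TTCCCC	TAGAAG	17	this study; 150 nt upstream of ileS
lspA	M. extorquens AM1	primer extension	P_orf181				129	TCGACG	GGTGCC	19	faint primer extension band; low promoter activity
mxaF	M. extorquens DM4	dRNA-seq		chromosome	5068109	-	168	AAGACA	TAGAAA	18	this study; TSS position 5068109 (minus)
mxaF	M. extorquens AM1	nuclease S1					167	AAGACA	TAGAAA	18	reported 167-168; also seen by run-off; mxaF also named moxF
mxaF	M. organophilum XX	primer extension					170	AAGACA	TAGAAA	18	
mxaW	M. extorquens DM4	dRNA-seq		chromosome	5068271	+	41	TTGACC	ACCGTT	18	this study; TSS position 5068271 (plus)
mxaW	M. extorquens AM1	primer extension					52	TTGGCA	ACCCAT		spacer not determined; sequence not found in AM1 genome
mxaW	M. organophilum XX	primer extension					54	TTGACC	ACCACT	18	
mtkA	M. extorquens DM4	dRNA-seq		chromosome	2393413	+	31	TTCCCG	GAAGGT	17	this study; TSS position 2393413 (plus)
mtkA	M. extorquens AM1	primer extension	Pqsc2-1				46	TTGAGA	AGTAAT	19	qsc2 operon (mtkA-mtkB-ppc-mcl)
mtkA	M. extorquens AM1	primer extension	Pqsc2-2				80	AAGTCA	AAGAAA	30	30 nt spacer found in AM1 genome sequence
pqqA	M. extorquens DM4	dRNA-seq	P_mxbM	chromosome	2416334	-	119	TGGCGC	TGATGG	19	this study; upstream of adjacent gene mxbM
pqqA	M. extorquens AM1	primer extension	P_pqqD				95	TTGCAG	CGATAT	16	promoter checked using xylE fusion
sga	M. extorquens DM4	dRNA-seq	P_sga	chromosome	2388788	+	46	TTGCGC	CGGGAT	16	this study; TSS position 2388788 (plus, P class)
sga	M. extorquens DM4	dRNA-seq	P_qsc1	chromosome	2388435	+	356	GTGCCC	CCGGCA	18	this study; TSS position 2388435 (plus, orphan class)
sga	M. extorquens AM1	primer extension	P_qsc1				343	TTGAAT	CATCGA	17	qsc1 operon (sga-hpr-mtdA-fch)
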