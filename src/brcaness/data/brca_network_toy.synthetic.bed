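chr1	3000000	3100000	BRCA1
chr2	3000000	3100000	BRCA2
chr3	3000000	3100000	TP53
chr4	3000000	3100000	RB1
chr5	3000000	3100000	PTEN
chr1	20428571	20528571	PALB2
chr2	16857142	16957142	CHEK2
chr3	13285714	13385714	ATM
chr4	9714285	9814285	ATR
chr5	6142857	6242857	BAP1
chr1	37857142	37957142	BARD1
chr2	30714284	30814284	BRIP1
chr3	23571428	23671428	RAD51
chr4	16428570	16528570	RAD51B
chr5	9285714	9385714	RAD51C
chr1	55285713	55385713	RAD51D
chr2	44571426	44671426	RAD52
chr3	33857142	33957142	RAD54L
chr4	23142855	23242855	XRCC2
chr5	12428571	12528571	XRCC3
chr1	72714284	72814284	MRE11
chr2	58428568	58528568	RAD50
chr3	44142856	44242856	NBN
chr4	29857140	29957140	FANCA
chr5	15571428	15671428	FANCB
chr1	90142855	90242855	FANCC
chr2	72285710	72385710	FANCD2
chr3	54428570	54528570	FANCE
chr4	36571425	36671425	FANCF
chr5	18714285	18814285	FANCG
chr1	107571426	107671426	FANCI
chr2	86142852	86242852	FANCL
chr3	64714284	64814284	FANCM
chr4	43285710	43385710	MDC1
chr5	21857142	21957142	NUMA1
chr1	124999997	125099997	WRN
chr2	99999994	100099994	BLM
chr3	74999998	75099998	RECQL4
chr4	49999995	50099995	RECQL5
chr5	24999999	25099999	MUTYH
chr1	142428568	142528568	CHEK1
chr2	113857136	113957136	CDK12
chr3	85285712	85385712	ABRAXAS1
chr4	56714280	56814280	UIMC1
chr5	28142856	28242856	BABAM1
chr1	159857139	159957139	BABAM2
chr2	127714278	127814278	BRCC3
chr3	95571426	95671426	RBBP7
chr4	63428565	63528565	RBBP4
chr5	31285713	31385713	NCOA2
chr1	177285710	177385710	CSTF2
chr2	141571420	141671420	XIST
chr3	105857140	105957140	AR
chr4	70142850	70242850	H2AFX
chr5	34428570	34528570	TP53BP1
chr1	194714281	194814281	RIF1
chr2	155428562	155528562	RNF8
chr3	116142854	116242854	RNF168
chr4	76857135	76957135	UBE2T
chr5	37571427	37671427	USP1
chr1	212142852	212242852	HELQ
chr2	169285704	169385704	POLQ
chr3	126428568	126528568	PARP1
chr4	83571420	83671420	PARP2
chr5	40714284	40814284	EME1
chr1	229571423	229671423	MUS81
chr2	183142846	183242846	GEN1
chr3	136714282	136814282	SLX4
chr4	90285705	90385705	ERCC4
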