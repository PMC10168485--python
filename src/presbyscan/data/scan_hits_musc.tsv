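coordinate	variant_id	ref	alt	gene	effect	sex_difference	replication
1:1485777	rs1622213	G	A	ATAD3B	Worse		Like homozygous reference (2 carriers)
1:158093761	rs139995772	C	T	KIRREL1	Better		Different (1 carrier; worse hearing)
1:230772053	rs28359655	C	T	CAPN9	Worse	No female carriers	Not comparable
1:32695311	rs41265855	G	A	SYNC	Better		No
1:54096337	rs41294786	C	G	TCEANC2	Better		No
2:128268653	rs3958533	G	T	HS6ST1	Worse	Only seen in men	No
3:151190791	rs34501514	G	T	MED12L	Better		Similar thresholds (1 carrier)
3:39107084	rs575892658	T	A	GORASP1	Better		No
4:108014444	rs61735992	T	G	HADH	Worse	Only seen in women	Similar thresholds (5 carriers, significant in Twins UK)
6:166382716	rs550593206	C	A	MPC1	Worse	Only seen in women	No
6:77463033	rs130060	A	C	HTR1B	Worse		Variable but like homozygous reference (7 carriers)
7:107975743	rs28750165	G	A	LAMB1	Better		No
7:1547804	rs61747419	G	A	TMEM184A	Worse		No
7:73769649	rs139191328	G	A	CLDN3	Worse		No
9:105635214	rs41313301	A	G	FKTN	Better	Only seen in men	Not comparable
9:108862962	rs41278347	G	A	ACTL7A	Worse		Different (2 carriers; better hearing)
9:15874587	rs149814894	T	G	CCDC171	Worse	Only seen in men	Not comparable
9:420579	rs116920018	A	G	DOCK8	Worse		Like homozygous reference (4 carriers)
10:112445316	rs34350728	C	T	ZDHHC6	Better		Similar thresholds (3 carriers)
10:132885887	rs150871636	T	C	CFAP46	Worse		No
10:97458699	rs36023427	C	T	MMS19	Worse	Only seen in men	No
11:40116285	rs144974170	T	G	LRRC4C	Better		Different (1 carrier; worse hearing)
11:57301020	rs139208640	G	A	TNKS1BP1	Worse		Variable between left and right ears (2 carriers)
12:122340851	rs61954403	C	T	CLIP1	Worse	Only seen in women	Like homozygous reference (5 carriers)
14:21000977	rs72684072	T	A	SLC39A2	Worse		Like homozygous reference (4 carriers)
14:45242137	rs34168608	G	C	MIS18BP1	Worse	Only seen in men	Not comparable
14:54531033	rs34839928	C	T	CGRRF1	Worse	Only seen in women	Like homozygous reference (2 carriers)
14:60027961	rs368587449	C	T	LRRC9	Better		No
16:15036070	rs148061029	G	A	PDXDC1	Better		No
16:2181024	rs183093419	T	C	CASKIN1	Better		No
16:70156611	rs117263218	G	A	PDPR	Worse	Only seen in women	Different (2 carriers; better hearing)
16:88721827	rs139051768	G	A	PIEZO1	Worse		Like homozygous reference (2 homozygous carriers, 1 heterozygous)
17:40487189	rs144692706	C	T	TNS4	Worse	Only seen in men	Not comparable
17:58195140	rs35617692	C	A	EPX	Worse	Only seen in women	Variable between left and right ears (2 carriers)
18:70197682	rs12956068	T	G	RTTN	Worse		No
19:10224049	rs117064827	A	G	S1PR2	Worse	Only seen in men	Not comparable
19:13882951	rs77270337	G	A	C19orf57 (BRME1)	Better	Only seen in men	Not comparable
20:3691399	rs143489222	C	T	SIGLEC1	Better		No
20:54171651	rs35873579	G	A	CYP24A1	Better		Different (1 carrier; worse hearing)
20:62351710	rs78026347	G	A	LAMA5	Worse		Different (2 carriers; better hearing)
MT:15257	.	G	A	MT-CYB	Better	Only seen in men	No
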