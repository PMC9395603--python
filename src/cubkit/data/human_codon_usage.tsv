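# Homo sapiens codon usage reference table, v1
# Source: Codon Usage Database (https://www.kazusa.or.jp/codon/), species
# Homo sapiens [gbpri], 93487 CDSs, 40662582 codons, GenBank release 160.
# Columns: DNA codon, one-letter amino acid (* = stop), frequency per
# thousand codons, approximate count. Counts are derived here as
# round(freq_per_1000 * 40662582 / 1000); the database publishes exact
# counts, but only frequencies are used downstream (relative adaptiveness
# depends on within-family ratios only).
codon	aa	freq_per_1000	count
TTT	F	17.6	715661
TTC	F	20.3	825450
TTA	L	7.7	313102
TTG	L	12.9	524547
CTT	L	13.2	536746
CTC	L	19.6	796987
CTA	L	7.2	292771
CTG	L	39.6	1610238
ATT	I	16.0	650601
ATC	I	20.8	845782
ATA	I	7.5	304969
ATG	M	22.0	894577
GTT	V	11.0	447288
GTC	V	14.5	589607
GTA	V	7.1	288704
GTG	V	28.1	1142619
TCT	S	15.2	618071
TCC	S	17.7	719728
TCA	S	12.2	496084
TCG	S	4.4	178915
CCT	P	17.5	711595
CCC	P	19.8	805119
CCA	P	16.9	687198
CCG	P	6.9	280572
ACT	T	13.1	532680
ACC	T	18.9	768523
ACA	T	15.1	614005
ACG	T	6.1	248042
GCT	A	18.4	748192
GCC	A	27.7	1126354
GCA	A	15.8	642469
GCG	A	7.4	300903
TAT	Y	12.2	496084
TAC	Y	15.3	622138
TAA	*	1.0	40663
TAG	*	0.8	32530
CAT	H	10.9	443222
CAC	H	15.1	614005
CAA	Q	12.3	500150
CAG	Q	34.2	1390660
AAT	N	17.0	691264
AAC	N	19.1	776655
AAA	K	24.4	992167
AAG	K	31.9	1297136
GAT	D	21.8	886444
GAC	D	25.1	1020631
GAA	E	29.0	1179215
GAG	E	39.6	1610238
TGT	C	10.6	431023
TGC	C	12.6	512349
TGA	*	1.6	65060
TGG	W	13.2	536746
CGT	R	4.5	182982
CGC	R	10.4	422891
CGA	R	6.2	252108
CGG	R	11.4	463553
AGT	S	12.1	492017
AGC	S	19.5	792920
AGA	R	12.2	496084
AGG	R	12.0	487951
GGT	G	10.8	439156
GGC	G	22.2	902709
GGA	G	16.5	670933
GGG	G	16.5	670933
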