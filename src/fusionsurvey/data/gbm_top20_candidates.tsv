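fusion_type	gene1	gene2	sample	resper	inter_reads	known	amplicon	misannotation	in_frame	junction_reads
read-through	FGFR3	TACC3	1835	108.2	40	1	0	0	1	60
intra	EGFR	CO9	5209	89.3	35	0	1	0	1	10
read-through	KIF5A	BC033961	0618	74.5	30	0	0	1	1	8
intra	DTX3	FRS2	2571	74.0	28	0	0	0	0	5
read-through	VSTM2A	EGFR	0747	72.9	27	0	1	0	1	9
read-through	EGFR	LANCL2	0211	67.5	25	0	1	0	1	7
intra	AK293540	AGAP3	2528	63.7	24	0	0	0	0	4
cis	LANCL2	PSPH	0817	52.8	20	0	1	0	1	6
intra	BCAN	NTRK1	2619	50.7	19	0	0	0	1	120
cis	LANCL2	SEPT14	0211	48.6	18	0	1	0	1	5
cis	SEC61G	EGFR	2554	45.5	17	0	1	0	1	4
intra	SDK1	EGFR	2557	38.3	14	0	1	0	1	3
intra	MARCH9	SUDS3	5856	36.6	13	0	0	0	1	0
read-through	KIF5A	BC033961	1980	34.9	13	0	0	1	1	6
read-through	FGFR3	TACC3	4925	32.4	12	1	0	0	1	20
cis	OS9	C12orf66	0174	31.8	12	0	0	0	0	3
intra	NFASC	NTRK1	5411	31.7	12	0	0	0	1	500
read-through	KIF5A	BC033961	5651	30.4	11	0	0	1	1	5
intra	YEATS4	XRCC6BP1	0138	30.4	11	0	0	0	1	25
read-through	KIF5A	BC033961	2558	29.3	11	0	0	1	1	4
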