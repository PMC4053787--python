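# Structural variants between C57BL/6N and C57BL/6J; coordinates taken as 1-based inclusive on NCBIM37/mm9 (footnote defining the convention unavailable; declared here); strain = carrier of the derived allele as printed
chrom	start	stop	ancestral_event	strain_label	strain_primary	gene	overlap
1	149518394	149524878	LINE Ins	B6J	B6J		none
2	7325700	7330977	IAP Ins	B6J	B6J		none
2	70619835	70620080	SINE Ins	B6J	B6J	Tlk1	intron
3	77975065	77977953	Del	B6N	B6N		none
3	5049018	5055845	LINE Ins	B6J	B6J		none
3	60336036	60336037	Del (large)	B6J	B6J	Mbnl1	intron
3	41885819	41887255	LINE Ins	B6J	B6J		none
3	18484710	18484889	Del	B6N	B6N		none
4	101954274	101954395	Del	B6N	B6N	Pde4b	intron
4	116051393	116051799	MaLR Ins	B6J	B6J	Mast2	intron
5	46376307	46377852	LINE Ins	B6J	B6J		none
5	90356490	90356491	Del (~300 bp)	B6J	B6J		none
5	146248861	146261885	Ins	B6J+others	B6J		none
6	18112291	18119019	LINE Ins	B6J	B6J		none
6	62964974	62972907	LINE Ins	B6J	B6J		none
6	86478779	86479400	Ins	B6J	B6J		none
6	103669536	103676487	LINE Ins	B6J	B6J	Chl1	intron
6	104207081	104214434	LINE Ins	B6J	B6J		none
7	92095990	92096149	Del	B6N	B6N	Vmn2r65	exon
7	27636128	27748456	Ins	B6J	B6J	Cyp2a22	entire
7	100892501	100899058	LINE Ins	B6J	B6J		none
7	139306094	139307981	MaLR Ins	B6J	B6J	Cpxm2	intron
8	16716381	16716382	Del (large)	B6J	B6J	Csmd1	intron
9	25674550	25674770	SINE Ins	B6J	B6J		none
9	58544415	58546304	MaLR Ins	B6J	B6J	2410076I21Rik	intron
10	3039196	3039197	Del (large)	B6J	B6J		none
10	29339441	29345955	LINE Ins	B6J	B6J		none
10	32536420	32543464	LINE Ins	B6J	B6J	Nkain2	intron
10	49543303	49550645	LINE Ins	B6J	B6J		none
11	104906390	104906621	Del	B6N	B6N		none
11	119560391	119566827	MTA Ins	B6J	B6J	Rptor	intron
12	42023964	42032747	Del	B6N	B6N	Immp2l	intron
13	71224557	71231011	MTA Ins	B6J	B6J		none
13	120164268	120164269	Del (large)	B6J	B6J	Nnt	exon
14	112825585	112832341	LINE Ins	B6J	B6J		none
15	49554596	49554597	Ins (large)	B6N	B6N		none
15	31106173	31106382	VNTR				none
16	6115804	6138105	Del	B6N	B6N		none
17	60286367	60286368	Ins (~2000 bp)	B6N	B6N		none
18	4809271	4809272	Del (~1200 bp)	B6J	B6J		none
19	12863187	12863188	Del (~1800 bp)	B6J	B6J	Zfp91	intron
X	15697909	15697910	Del (~400 bp)	B6J	B6J		none
X	95155499	95163160	LINE Ins	B6J	B6J		none
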