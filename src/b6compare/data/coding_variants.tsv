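# Coding SNPs and small indels distinguishing C57BL/6N from C57BL/6J; coordinates 1-based on NCBIM37/mm9; '-' = absent/deleted allele
chrom	pos	base_j	base_n	strain_label	private_to	gene	consequence	aa_j	aa_n	note
13	65023280	C	T	B6N	B6N	Spata31	nonsense	Arginine	(stop)	
1	59904011	G	A	B6N	B6N	Bmpr2	missense	Arginine	Glutamine	
3	95538799	T	C	B6J	B6J	Ecm1	missense	Isoleucine	Valine	
3	96658480	A	G	B6J	B6J	Pdzk1	missense	Asparagine	Aspartic acid	
4	21800831	C	G	B6J	B6J	Sfrs18	missense	Arginine	Glycine	
4	137777588	C	T	B6N	B6N	Hp1bp3	missense	Leucine	Phenylalanine	
4	140354038	A	G	B6N	B6N	Padi3	missense	Leucine	Proline	
4	148318468	T	C	B6J	B6J	Casz1	missense	Leucine	Proline	
5	90204376	C	T	B6N	B6N	Adamts3	missense	Valine	Isoleucine	
5	97187161	T	C	B6J	B6J	Fras1	missense	Leucine	Proline	
5	113191741	C	T	B6N	B6N	Myo18b	missense	Arginine	Histidine	
6	39350455	T	A	B6J	B6J	Mkrn1	missense	Asparagine	Tyrosine	
7	3222538	T	C	B6J	B6J	Nlrp12	missense	Lysine	Arginine	
7	63386662	G	A	B6J	B6J	Herc2	missense	Glycine	Aspartic acid	
7	86256240	A	C	B6J	B6J	Acan	missense	Histidine	Proline	
7	110121823	C	T	B6N	B6N	Olfr577	missense	Valine	Isoleucine	
7	127278693	G	A	B6N+Spretus	B6N_shared	Zp2	missense	Alanine	Valine	
7	129311164	C	T	B6N	B6N	Plk1	missense	Arginine	Tryptophan	
9	24935069	C	G	B6N	B6N	Herpud2	missense	Valine	Leucine	
10	66700922	T	C	B6J	B6J	Jmjd1c	missense	Leucine	Proline	
10	78632222	A	G	B6N	B6N	Vmn2r80	missense	Asparagine	Serine	
10	87554578	T	C	B6N	B6N	Pmch	missense	Isoleucine	Threonine	
11	46036117	G	A	B6N	B6N	Cyfip2	missense	Serine	Phenylalanine	
11	90341985	C	T	B6N	B6N	Stxb4	missense		Threonine	as_printed_anomaly
13	21560172	A	G	B6J	B6J	Nkapl	missense	Glycine	Arginine	
13	73465884	A	G	B6J	B6J	Ndufs6	missense	Valine	Alanine	
13	93833534	C	G	B6J	B6J	Cmya5	missense	Alanine	Proline	
14	70986011	G	T	B6N	B6N	Fam160b2	missense	Serine	Arginine	
15	11266138	G	T	B6N	B6N	Adamts12	missense	Cysteine	Phenylalanine	
15	77468437	A	C	B6J	B6J	Apol11b	missense	Isoleucine	Arginine	
16	35291630	G	A	B6N	B6N	Adcy5	missense	Valine	Methionine	
17	47537359	T	C	B6J	B6J	Guca1a	missense	Isoleucine	Valine	
X	131227581	C	A	B6N	B6N	Armcx4	missense	Alanine	Aspartic acid	
5	54280548	A	G	B6J	B6J	Tbc1d19	splice			
1	141133664	G	-	B6N	B6N	Crb1	frameshift			
9	65127938	G	-	B6J	B6J	Cilp	frameshift			
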