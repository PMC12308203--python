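# Putoidae reference mitogenome feature table (genome length 18,830 bp, circular).
# Columns: gene, strand (J major / N minor), 1-based inclusive coordinates,
# printed length, anticodon triplet and its genome location, start/stop codon,
# printed signed intergenic nucleotides to the previous feature ("-" = none printed).
gene	strand	start	end	printed_length	anticodon	anticodon_start	anticodon_end	start_codon	stop_codon	printed_intergenic
COI	J	1	1551	1551	-	-	-	ATT	TAA	0
trnL2	J	1560	1623	64	TAA	1592	1594	-	-	8
trnD	J	1626	1685	60	GTC	1663	1665	-	-	2
ATP8	J	1686	1826	141	-	-	-	ATT	TAA	0
ATP6	J	1820	2431	612	-	-	-	ATG	TAA	-7
COIII	J	2463	3215	753	-	-	-	ATG	TAA	31
trnA	J	3200	3275	76	TGC	3237	3239	-	-	-15
trnR	J	3268	3312	45	TCG	3294	3296	-	-	-4
trnN	J	3322	3378	57	GTT	3343	3345	-	-	9
trnE	J	3376	3431	56	TTC	3406	3408	-	-	-3
trnF	N	3432	3496	66	GAA	3449	3451	-	-	0
trnH	N	3518	3587	69	GTG	3552	3554	-	-	21
ND6	J	3586	4065	480	-	-	-	ATT	TAA	-2
trnS1	J	4068	4124	57	TGA	4085	4087	-	-	2
trnQ	N	4152	4205	54	TTG	4186	4188	-	-	27
ND1	N	4218	5120	903	-	-	-	ATT	TAA	12
trnL1	N	5120	5194	75	TAG	5155	5157	-	-	-1
lrRNA	N	5195	6388	1194	-	-	-	-	-	0
trnV	N	6389	6452	64	TAC	6416	6418	-	-	0
trnI	J	6504	6573	70	GAT	6539	6541	-	-	51
trnM	J	6574	6639	65	CAT	6607	6609	-	-	0
ND2	J	6640	7581	942	-	-	-	ATT	TAA	0
trnW	J	7580	7635	56	TCA	7612	7614	-	-	-2
trnY	N	7634	7704	71	GTA	7668	7670	-	-	-2
COII	J	7777	8448	672	-	-	-	ATA	TAA	72
trnK	J	8450	8519	70	TTT	8510	8512	-	-	1
trnG	J	8557	8612	56	TCC	8587	8589	-	-	37
ND3	J	8610	8963	354	-	-	-	ATA	TAA	-3
trnS2	J	8959	9012	58	TCT	8986	8988	-	-	-5
ND5	N	9034	10662	1629	-	-	-	ATT	TAA	17
ND4	N	10650	11918	1269	-	-	-	ATT	TAA	-13
ND4L	N	11914	12207	294	-	-	-	ATT	TAA	-5
trnT	J	12190	12248	59	TGT	12222	12224	-	-	-18
trnP	N	12247	12303	57	AGG	12269	12271	-	-	-2
trnC	N	12282	12321	40	GCA	12302	12304	-	-	-22
cytb	J	12336	13418	1083	-	-	-	ATG	TAA	14
srRNA	N	15769	16377	609	-	-	-	-	-	2350
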