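# Published codon usage of the 13 protein-coding genes of the Putoidae
# reference mitogenome under the invertebrate mitochondrial code
# (RNA codons; printed RSCU to 2 decimals kept for cross-checks).
codon	amino_acid	count	printed_rscu
UUU	F	325	1.75
UUC	F	47	0.25
UUA	L	406	4.93
UUG	L	24	0.29
CUU	L	25	0.30
CUC	L	4	0.05
CUA	L	34	0.41
CUG	L	1	0.01
AUU	I	522	1.85
AUC	I	41	0.15
AUA	M	504	1.92
AUG	M	21	0.08
GUU	V	34	2.34
GUC	V	3	0.21
GUA	V	19	1.31
GUG	V	2	0.14
UAU	Y	238	1.86
UAC	Y	18	0.14
UAA	*	69	1.79
UAG	*	8	0.21
CAU	H	28	1.75
CAC	H	4	0.25
CAA	Q	30	1.88
CAG	Q	2	0.13
AAU	N	375	1.82
AAC	N	38	0.18
AAA	K	157	1.89
AAG	K	9	0.11
GAU	D	37	1.85
GAC	D	3	0.15
GAA	E	44	1.83
GAG	E	4	0.17
UCU	S	48	1.81
UCC	S	7	0.26
UCA	S	85	3.21
UCG	S	2	0.08
AGU	S	19	0.72
AGC	S	1	0.04
AGA	S	43	1.62
AGG	S	7	0.26
ACU	T	24	1.88
ACC	T	3	0.24
ACA	T	24	1.88
ACG	T	0	0.00
GCU	A	10	2.50
GCC	A	2	0.50
GCA	A	4	1.00
GCG	A	0	0.00
UGU	C	10	1.67
UGC	C	2	0.33
UGA	W	57	1.93
UGG	W	2	0.07
CGU	R	7	1.47
CGC	R	0	0.00
CGA	R	11	2.32
CGG	R	1	0.21
CCU	P	22	1.66
CCC	P	10	0.75
CCA	P	21	1.58
CCG	P	0	0.00
GGU	G	17	1.10
GGC	G	3	0.19
GGA	G	36	2.32
GGG	G	6	0.39
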