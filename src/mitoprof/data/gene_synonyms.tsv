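# Gene-label normalization map: common annotation-pipeline and GenBank
# spellings on the left, controlled vocabulary on the right. Matching is
# case-insensitive; hyphens/underscores in the raw label are ignored.
raw	canonical
COX1	COI
COX2	COII
COX3	COIII
CO1	COI
CO2	COII
CO3	COIII
COB	cytb
CYTB	cytb
CYB	cytb
NAD1	ND1
NAD2	ND2
NAD3	ND3
NAD4	ND4
NAD4L	ND4L
NAD5	ND5
NAD6	ND6
ATP6	ATP6
ATP8	ATP8
ATPASE6	ATP6
ATPASE8	ATP8
RRNL	lrRNA
RRNS	srRNA
16S	lrRNA
12S	srRNA
LRRNA	lrRNA
SRRNA	srRNA
RRN16	lrRNA
RRN12	srRNA
TRNL1	trnL1
TRNL2	trnL2
TRNS1	trnS1
TRNS2	trnS2
TRNLUAG	trnL1
TRNLUAA	trnL2
TRNSUCU	trnS1
TRNSUGA	trnS2
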