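# Published nucleotide composition of the Putoidae reference mitogenome,
# one row per partition: percentages to 1 decimal, skews to 3 decimals.
partition	pct_t	pct_c	pct_a	pct_g	pct_at	at_skew	gc_skew
whole_genome	44.6	6.8	46.2	2.4	90.7	0.017	-0.475
pcg	47.8	6.1	41.2	5.0	88.9	-0.074	-0.096
pcg_pos1	37.9	5.6	50.2	6.3	88.1	0.141	0.057
pcg_pos2	56.5	7.4	29.9	6.2	86.4	-0.308	-0.083
pcg_pos3	48.9	5.2	43.4	2.5	92.3	-0.060	-0.353
pcg_J	45.3	8.3	42.3	4.1	87.6	-0.035	-0.346
pcg_J_pos1	33.0	7.7	54.3	5.0	87.3	0.244	-0.211
pcg_J_pos2	54.8	10.0	28.9	6.3	83.7	-0.309	-0.229
pcg_J_pos3	48.2	7.3	43.6	0.9	91.8	-0.051	-0.781
pcg_N	51.6	2.4	39.4	6.5	91.1	-0.134	0.464
pcg_N_pos1	45.6	2.3	43.7	8.4	89.4	-0.021	0.572
pcg_N_pos2	59.2	3.1	31.5	6.2	90.8	-0.306	0.333
pcg_N_pos3	50.1	1.8	43.0	5.1	93.0	-0.075	0.474
trna	44.6	3.1	47.9	4.4	92.5	0.036	0.172
trna_J	44.1	4.1	48.3	3.6	92.4	0.045	-0.065
trna_N	45.5	1.4	47.3	5.8	92.8	0.020	0.600
rrna	46.3	2.4	44.6	6.8	90.8	-0.018	0.479
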