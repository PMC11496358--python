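gene_id	locus	mhc_class	cnv	n	n_snps	n_snps_nonsynonymous	pi	n_alleles	allelic_diversity
MHCI1	UI	I	False	876	1	1	0.00045	2	0.483
MHCI2	UD	I	False	876	1	0	0.00036	2	0.37
MHCI4	UA	I	True	611	53	36	0.01914	27	0.888
MHCI5	UK	I	False	874	4	4	0.00121	2	0.33
MHCI8	UC	I	False	822	2	1	0.00068	4	0.603
MHCI9	UE	I	False	814	4	2	0.00128	6	0.703
MHCI10	UF	I	False	876	2	1	0.00054	3	0.524
MHCI12	UH	I	True	363	50	21	0.01948	13	0.787
MHCI13	UG	I	True	825	15	12	0.00267	7	0.602
MHCI15	UJ	I	False	875	1	0	0.00052	2	0.499
MHCI19	UB	I	True	785	10	4	0.00333	7	0.802
DAA	DAA	II	False	876	5	0	0.00313	4	0.569
DAB2	DAB2	II	True	611	12	7	0.00682	18	0.869
DAB3	DAB3	II	True	599	27	20	0.01521	25	0.821
DAB4	DAB4	II	False	875	3	1	0.00149	3	0.407
DAB5	DAB5	II	False	876	2	2	0.00081	3	0.589
DBA1	DBA1	II	False	812	18	12	0.00793	11	0.738
DBA2	DBA2	II	True	835	23	17	0.01052	8	0.569
DBB2	DBB2	II	True	869	5	4	0.00148	2	0.245
DBB3	DBB3	II	True	840	12	7	0.00462	12	0.732
DCA	DCA	II	False	873	8	4	0.00347	6	0.757
DCB	DCB	II	False	876	5	4	0.00173	5	0.712
DMA	DMA	II	False	876	3	1	0.00134	3	0.598
DMB	DMB	II	False	768	3	3	0.00141	5	0.764
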