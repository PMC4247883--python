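snp_id	locus	effect_allele	other_allele	weight	ref_eaf
rs9939609	FTO	A	T	NA	0.42
rs2867125	TMEM18	C	T	NA	0.83
rs571312	MC4R	A	C	NA	0.24
rs10938397	GNPDA2	G	A	NA	0.43
rs10767664	BDNF	A	T	NA	0.78
rs2815752	NEGR1	A	G	NA	0.61
rs7359397	SH2B1	T	C	NA	0.40
rs9816226	ETV5	T	A	NA	0.82
rs3817334	MTCH2	T	C	NA	0.41
rs29941	KCTD15	G	A	NA	0.67
rs543874	SEC16B	G	A	NA	0.19
rs987237	TFAP2B	G	A	NA	0.18
rs7138803	FAIM2	A	G	NA	0.38
rs10150332	NRXN3	C	T	NA	0.21
rs713586	RBJ	C	T	NA	0.47
rs12444979	GPRC5B	C	T	NA	0.87
rs2241423	MAP2K5	G	A	NA	0.78
rs2287019	QPCTL	C	T	NA	0.80
rs1514175	TNNI3K	A	G	NA	0.43
rs13107325	SLC39A8	T	C	NA	0.07
rs2112347	FLJ35779	T	G	NA	0.63
rs10968576	LRRN6C	G	A	NA	0.31
rs3810291	TMEM160	A	G	NA	0.67
rs11847697	PRKD1	T	C	NA	0.04
rs2890652	LRP1B	C	T	NA	0.18
rs1555543	PTBP2	C	A	NA	0.59
rs4771122	MTIF3	G	A	NA	0.24
rs4929949	RPL27A	C	T	NA	0.52
rs206936	NUDT3	G	A	NA	0.21
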