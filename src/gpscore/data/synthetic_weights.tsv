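snp_id	weight
rs9939609	0.39
rs2867125	0.31
rs571312	0.22
rs10938397	0.18
rs10767664	0.18
rs2815752	0.13
rs7359397	0.15
rs9816226	0.14
rs3817334	0.06
rs29941	0.06
rs543874	0.22
rs987237	0.13
rs7138803	0.12
rs10150332	0.13
rs713586	0.14
rs12444979	0.16
rs2241423	0.13
rs2287019	0.15
rs1514175	0.07
rs13107325	0.19
rs2112347	0.10
rs10968576	0.11
rs3810291	0.09
rs11847697	0.17
rs2890652	0.11
rs1555543	0.07
rs4771122	0.09
rs4929949	0.06
rs206936	0.06
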