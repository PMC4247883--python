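snp_id	n0	n1	n2
rs9939609	278	370	106
rs2867125	21	212	520
rs571312	454	267	31
rs10938397	256	380	107
rs10767664	31	219	496
rs2815752	69	299	372
rs7359397	547	186	17
rs9816226	40	252	448
rs3817334	260	335	160
rs29941	59	284	417
rs543874	522	220	18
rs987237	552	176	28
rs7138803	359	319	73
rs10150332	455	256	38
rs713586	203	375	163
rs12444979	8	144	607
rs2241423	58	274	419
rs2287019	34	223	484
rs1514175	229	358	170
rs13107325	730	33	0
rs2112347	78	298	364
rs10968576	590	147	19
rs3810291	209	356	190
rs11847697	569	166	17
rs2890652	526	212	19
rs1555543	238	378	129
rs4771122	500	225	27
rs4929949	277	325	142
rs206936	344	323	79
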