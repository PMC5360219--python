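variant	chromosome	position	gene	beta	neg_log10_p
apoe_e2	19		APOE	-0.47	15.0
apoe_e4	19		APOE	1.03	20.0
rs4266886	1	207685786	CR1	-0.09	2.7
rs61822977	1	207796065	CR1	-0.08	2.8
rs6733839	2	127892810	BIN1	-0.15	10.5
rs10202748	2	234003117	INPP5D	-0.06	2.1
rs115124923	6	32510482	HLA-DRB5	0.17	7.4
rs115675626	6	32669833	HLA-DQB1	-0.11	3.2
rs1109581	6	47678182	GPR115	-0.07	2.6
rs17265593	7	37619922	BC043356	-0.23	3.6
rs2597283	7	37690507	BC043356	0.28	4.7
rs1476679	7	100004446	ZCWPW1	0.11	4.9
rs78571833	7	143122924	AL833583	0.14	3.8
rs12679874	8	27230819	PTK2B	-0.09	4.2
rs2741342	8	27330096	CHRNA2	0.09	2.9
rs7831810	8	27430506	CLU	0.09	3.0
rs1532277	8	27466181	CLU	0.21	8.3
rs9331888	8	27468862	CLU	0.16	5.1
rs7920721	10	11720308	CR595071	-0.07	2.9
rs3740688	11	47380340	SPI1	0.07	2.8
rs7116190	11	59964992	MS4A6A	0.08	3.9
rs526904	11	85811364	PICALM	-0.20	2.3
rs543293	11	85820077	PICALM	0.30	4.2
rs11218343	11	121435587	SORL1	0.18	2.8
rs6572869	14	53353454	FERMT2	-0.11	3.0
rs12590273	14	92934120	SLC24A4	0.10	3.5
rs7145100	14	107160690	abParts	0.08	2.0
rs74615166	15	64725490	TRIP4	-0.23	3.1
rs2526378	17	56404349	BZRAP1	0.09	4.9
rs117481827	19	1021627	C19orf6	-0.09	2.5
rs7408475	19	1050130	ABCA7	0.18	4.3
rs3752246	19	1056492	ABCA7	-0.25	8.4
rs7274581	20	55018260	CASS4	0.10	2.1
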