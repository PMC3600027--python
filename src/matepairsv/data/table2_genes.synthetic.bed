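2	175812451	175838951	CHN1	0	+	175812451	175838951	0	3	1000,1000,1000	0,19500,25500
17	57654081	57752581	CLTC	0	+	57654081	57752581	0	15	1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000	0,6000,12000,18000,24000,30000,36000,42000,48000,54000,60000,66000,72000,91500,97500
11	108510472	108591157	DDX10	0	+	108510472	108591157	0	12	1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000	0,6000,12000,18000,24000,30000,36000,42000,48000,54000,73685,79685
21	41839299	41877799	DSCAM	0	+	41839299	41877799	0	5	1000,1000,1000,1000,1000	0,6000,12000,31500,37500
4	66380361	66425143	EPHA5	0	-	66380361	66425143	0	5	1000,1000,1000,1000,1000	0,6000,31782,37782,43782
8	72159169	72225477	EYA1	0	+	72159169	72225477	0	9	1000,1000,1000,1000,1000,1000,1000,1000,1000	0,6000,12000,18000,24000,30000,36000,59308,65308
11	106569804	106629066	GUCY1A2	0	+	106569804	106629066	0	8	1000,1000,1000,1000,1000,1000,4762,1000	0,6000,12000,18000,24000,30000,48500,58262
5	134690921	134728308	H2AFY	0	-	134690921	134728308	0	4	1000,1000,1000,1000	0,6000,30387,36387
10	65185014	65211514	JMJD1C	0	+	65185014	65211514	0	3	1000,1000,1000	0,19500,25500
5	137659029	137752076	KDM3B	0	+	137659029	137752076	0	13	1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000	0,6000,12000,18000,24000,30000,36000,42000,48000,54000,60000,86047,92047
10	24411404	24446256	KIAA1217	0	-	24411404	24446256	0	4	1000,1000,1000,1000	0,6000,27852,33852
17	25873800	25912300	KSR1	0	+	25873800	25912300	0	5	1000,1000,1000,1000,1000	0,6000,12000,31500,37500
19	30312200	30362700	LCA10	0	+	30312200	30362700	0	7	1000,1000,1000,1000,1000,1000,1000	0,6000,12000,18000,24000,43500,49500
4	150997579	151306079	LRBA	0	+	150997579	151306079	0	50	1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000	0,6000,12000,18000,24000,30000,36000,42000,48000,54000,60000,66000,72000,78000,84000,90000,96000,102000,108000,114000,120000,126000,132000,138000,144000,150000,156000,162000,168000,174000,180000,186000,192000,198000,204000,210000,216000,222000,228000,234000,240000,246000,252000,258000,264000,270000,276000,282000,301500,307500
3	168868754	168901254	MECOM	0	+	168868754	168901254	0	4	1000,1000,1000,1000	0,6000,25500,31500
2	172874908	172901408	METAP1D	0	+	172874908	172901408	0	3	1000,1000,1000	0,19500,25500
21	47129998	47156498	PCBP3	0	+	47129998	47156498	0	3	1000,1000,1000	0,19500,25500
2	120282907	120342556	PCDP1	0	+	120282907	120342556	0	8	1000,1000,1000,1000,1000,1000,1000,1000	0,6000,12000,18000,24000,30000,52649,58649
12	48486176	48524676	PFKM	0	+	48486176	48524676	0	5	1000,1000,1000,1000,1000	0,6000,12000,31500,37500
10	22858924	22899865	PIP4K2A	0	+	22858924	22899865	0	5	1000,1000,1000,1000,1000	0,6000,12000,33941,39941
21	35898065	35924565	RCAN1	0	+	35898065	35924565	0	3	1000,1000,1000	0,19500,25500
15	60808616	61377011	RORA	0	-	60808616	61377011	0	4	1000,1000,1000,1000	0,6000,25500,567395
13	21698982	21760867	SKA3	0	-	21698982	21760867	0	6	1000,1000,1000,1000,1000,1000	0,36500,42885,48885,54885,60885
3	47781973	47814473	SMARCC1	0	+	47781973	47814473	0	4	1000,1000,1000,1000	0,6000,25500,31500
2	65538070	65570570	SPRED2	0	+	65538070	65570570	0	4	1000,1000,1000,1000	0,6000,25500,31500
15	71701637	71758137	THSD4	0	+	71701637	71758137	0	8	1000,1000,1000,1000,1000,1000,1000,1000	0,6000,12000,18000,24000,30000,49500,55500
17	38965873	38997373	TMEM99	0	+	38965873	38997373	0	4	1000,1000,1000,1000	0,6000,24500,30500
3	170779486	170871986	TNIK	0	+	170779486	170871986	0	14	1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000	0,6000,12000,18000,24000,30000,36000,42000,48000,54000,60000,66000,85500,91500
19	30920106	30958549	ZNF536	0	+	30920106	30958549	0	4	1000,1000,1000,1000	0,6000,31443,37443
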