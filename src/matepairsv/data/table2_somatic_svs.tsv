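type	sample	chrom1	pos1	chrom2	pos2	genes1	genes2
deletion	153 T	11	106618805	11	106622567	GUCY1A2|exon 7	GUCY1A2|exon 7
deletion	154 T	8	72214170	8	72217978	EYA1|intron 7–8	EYA1|intron 7–8
deletion	119 T	5	134715922	5	134720809	H2AFY|intron 2–3	H2AFY|intron 2–3
deletion	149 T	2	12526265	2	12528008
deletion	149 T	2	65366656	2	65369602
deletion	149 T	10	22889925	10	22892366	PIP4K2A|intron 3–4	PIP4K2A|intron 3–4
deletion	149 T	15	45915722	15	45917969
deletion	152 T	12	2130488	12	2133385
inversion	120 T	2	120331908	2	120335057	PCDP1|intron 6–7	PCDP1|intron 6–7
inversion	116 T	5	129549038	5	129552347
inversion	149 T	10	24436405	10	24438757	KIAA1217|intron 2–3	KIAA1217|intron 2–3
inversion	153 T	2	172893909	2	175831452	METAP1D|intron 1–2	CHN1|intron 1–2
inversion	116 T	3	168893755	3	170864487	MECOM|intron 2–3	TNIK|intron 12–13
inversion	151 T	5	137738030	5	137744577	KDM3B|intron 11–12	KDM3B|intron 11–12
translocation	153 T	2	42052398	4	66411362		EPHA5|intron 3–4
translocation	153 T	6	104501617	X	152223450
translocation	153 T	7	54909974	19	29832131
translocation	153 T	8	57916723	19	30951050		ZNF536|intron 2–3
translocation	153 T	12	48517177	19	30945107	PFKM|intron 3–4	ZNF536|intron 2–3
translocation	153 T	19	30355201	X	153152399	LCA10|intron 5–6
translocation	153 T	5	174245601	10	65204015		JMJD1C|intron 1–2
translocation	116 T	2	199768975	5	28258969
translocation	118 T	7	90081994	17	25904801		KSR1|intron 3–4
translocation	118 T	15	60231305	21	47148999		PCBP3|intron 1–2
translocation	118 T	15	60833617	21	35917066	RORA|intron 2–3	RCAN1|intron 1–2
translocation	118 T	15	61356378	21	41870300	RORA|intron 1–2	DSCAM|intron 3–4
translocation	118 T	15	61375512	21	27982153	RORA|intron 1–2
translocation	118 T	15	71750638	21	18023846	THSD4|intron 6–7
translocation	119 T	2	42052196	4	66411644		EPHA5|intron 3–4
translocation	119 T	4	4714578	17	38990874		TMEM99|exon 3
translocation	119 T	8	32833459	18	64563574
translocation	120 T	8	127068558	11	112588800
translocation	120 T	11	108583473	13	21735983	DDX10|intron 10–11	SKA3|exon 5
translocation	120 T	13	103233303	16	77586406
translocation	148 T	2	65563071	8	80378299	SPRED2|intron 2–3
translocation	148 T	9	13526912	17	57745082		CLTC|intron 13–14
translocation	149 T	1	247997045	10	27944748
translocation	149 T	3	47806974	4	151298580	SMARCC1|intron 2–3	LRBA|intron 48–49
translocation	149 T	5	15946143	17	67928932
translocation	149 T	11	108583658	13	21742368	DDX10|intron 10–11	SKA3|exon 4
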