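# Published sigma-S ChIP-seq binding-site tables, one row per candidate gene.
# table T1: peaks attributable to a single downstream gene (one row each).
# table T2: peaks between divergently transcribed genes (two rows per peak).
# Coordinates are 1-based inclusive on the E. coli K-12 MG1655 chromosome.
# tss: comma-separated experimentally validated TSS printed inside the peak
# ('.' = none printed). The ydbJ TSS printed for the ydbK/ydbJ pair is omitted:
# it lies 4 bp outside the peak and violates the containment contract.
# sigmaS_evidence: 1 when the source table flags prior sigma-S dependence for
# the gene (boldface rows plus dps, whose cited references are sigma-S studies).
table	peak_start	peak_end	gene_id	strand	tss	sigmaS_evidence	category
T1	63400	63538	hepA	-	.	0	unequivocal
T1	106436	106616	lpxC	+	106530	1	unequivocal
T1	262040	262202	thrW	+	.	0	unequivocal
T1	392250	392349	insEF-2	-	.	1	unequivocal
T1	406100	406199	yaiA	+	.	1	unequivocal
T1	437329	437469	yajO	-	.	1	unequivocal
T1	479920	480115	tomB	-	.	0	unequivocal
T1	574850	575099	insH-2	-	.	0	unequivocal
T1	837550	837849	ybiI	-	.	0	unequivocal
T1	848050	848349	dps	-	848173	1	unequivocal
T1	1215900	1216399	ymgC	+	.	1	unequivocal
T1	1219400	1219949	ycgH	.	.	0	unequivocal
T1	1236420	1236526	ycgB	-	1236508	1	unequivocal
T1	1341304	1341480	osmB	-	1341393	1	unequivocal
T1	1430250	1430549	tfaR	+	.	0	unequivocal
T1	1509526	1509697	ydcS	+	1509623	1	unequivocal
T1	1524000	1524199	ansP	-	1524035,1524044	1	unequivocal
T1	1608700	1608949	uxaB	-	1608744	0	unequivocal
T1	1687744	1687907	ydgA	+	1687818	1	unequivocal
T1	1755350	1755499	lpp	+	1755407	0	unequivocal
T1	1756820	1756885	ynhG	-	.	1	unequivocal
T1	1894663	1894896	sdaA	+	1894833	0	unequivocal
T1	1905547	1905784	yobF	-	1905641	0	unequivocal
T1	1920033	1920203	yebW	+	.	0	unequivocal
T1	1921150	1921299	ryeB	-	.	1	unequivocal
T1	2026384	2026505	yodC	-	.	1	unequivocal
T1	2061261	2061484	erfK	-	.	1	unequivocal
T1	2103850	2104199	wbbI	-	.	0	unequivocal
T1	2104550	2105599	wbbH	-	.	0	unequivocal
T1	2190800	2190949	yehE	-	.	0	unequivocal
T1	2225279	2225390	yohF	-	.	1	unequivocal
T1	2468677	2468882	tfaS	+	.	0	unequivocal
T1	2663364	2663501	csiE	+	2663423	1	unequivocal
T1	2734910	2735081	raiA	+	.	1	unequivocal
T1	2753502	2753707	ssrA	+	2753608	0	unequivocal
T1	2758300	2758999	yfjJ	+	.	1	unequivocal
T1	2797100	2797249	alaE	+	.	0	unequivocal
T1	2817227	2817395	csrA	-	2817295	1	unequivocal
T1	2924252	2924370	ygdH	+	.	1	unequivocal
T1	2974153	2974278	omrA	-	2974211	1	unequivocal
T1	2991100	2992299	ygeI	+	.	0	unequivocal
T1	3054792	3054952	sibC	+	3054873	0	unequivocal
T1	3058600	3058749	scpA	+	.	0	unequivocal
T1	3066050	3066149	yggE	-	3066148	1	unequivocal
T1	3235233	3235381	ygjR	+	3235304	0	unequivocal
T1	3598950	3599099	rpoH	-	.	1	unequivocal
T1	3637750	3637949	uspB	-	3637871	1	unequivocal
T1	3706750	3706999	proK	-	.	0	unequivocal
T1	4361287	4361432	yjdC	-	4361353	1	unequivocal
T1	4437000	4437349	ytfJ	-	4437309	1	unequivocal
T2	1257750	1258199	pth	-	1257765	0	divergent
T2	1257750	1258199	ychH	+	1257961	1	divergent
T2	1288250	1288399	ychJ	-	1288400	0	divergent
T2	1288250	1288399	rssA	+	1288329	1	divergent
T2	1438800	1439049	ydbK	-	.	0	divergent
T2	1438800	1439049	ydbJ	+	.	0	divergent
T2	1488650	1488949	gapC_1	-	.	1	divergent
T2	1488650	1488949	cybB	+	.	0	divergent
T2	1820250	1820349	osmE	-	1820307	1	divergent
T2	1820250	1820349	nadE	+	1820326	0	divergent
T2	2022850	2023149	dsrB	-	.	1	divergent
T2	2022850	2023149	yodD	+	.	1	divergent
T2	2493450	2493549	yfdY	-	.	0	divergent
T2	2493450	2493549	lpxP	+	.	1	divergent
T2	2627100	2627399	yfgF	-	.	0	divergent
T2	2627100	2627399	yfgG	+	2627275	0	divergent
T2	2903350	2903649	queE	-	.	0	divergent
T2	2903350	2903649	ygcG	+	.	1	divergent
T2	3851100	3851399	istR	-	3851215,3851280	0	divergent
T2	3851100	3851399	tisB	+	3851360	0	divergent
T2	4124850	4125049	priA	-	.	0	divergent
T2	4124850	4125049	rpmE	+	4124931	0	divergent
T2	4414650	4414899	bsmA	-	.	1	divergent
T2	4414650	4414899	yjfP	+	.	0	divergent
T2	4434400	4434749	cpdB	-	4434652	0	divergent
T2	4434400	4434749	cysQ	+	.	0	divergent
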