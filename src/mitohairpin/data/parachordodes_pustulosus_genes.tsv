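gene	strand	start	stop	class	start_codon	stop_codon
cox1	+	10	1542	PCG	ATG	TAA
cox2	+	1555	2232	PCG	ATG	TAA
trnK	+	2239	2300	tRNA
trnD	+	2310	2363	tRNA
atp8	+	2364	2483	PCG	ATC	TAA
atp6	+	2490	3173	PCG	ATG	TAA
cox3	+	3176	3967	PCG	ATG	TAA
trnG	+	3987	4044	tRNA
nad3	+	4045	4380	PCG	ATA	T
trnA	+	4382	4436	tRNA
trnR	+	4437	4487	tRNA
trnN	+	4489	4546	tRNA
trnS1	+	4548	4601	tRNA
nad4l	+	4602	4862	PCG	ATA	TAG
nad4	+	5003	6184	PCG	ATA	TAG
trnH	+	6176	6237	tRNA
nad5	+	6332	7660	PCG	TTA	TAA
trnF	+	7668	7722	tRNA
trnW	-	7719	7781	tRNA
nad2	-	7767	8738	PCG	TTA	TAA
trnM	-	8754	8816	tRNA
trnQ	+	8814	8872	tRNA
trnY	+	8885	8939	tRNA
trnT	+	8955	9010	tRNA
trnP	-	9017	9083	tRNA
nad6	+	9160	9702	PCG	ATA	TAA
cytb	+	9653	10765	PCG	ATA	TAG
trnS2	+	10765	10821	tRNA
trnE	+	10836	10897	tRNA
trnL1	-	10898	10963	tRNA
rrnL	-	10969	12037	rRNA
trnV	-	12038	12098	tRNA
rrnS	-	12093	12754	rRNA
trnC	-	12755	12810	tRNA
trnI	-	12822	12871	tRNA
nad1	-	12873	13778	PCG	TTG	TAG
trnL2	-	13782	13847	tRNA
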