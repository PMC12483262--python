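name	category	strand	start	end	size	start_codon	stop_codon	anticodon
trnI	tRNA	+	1	69	69			GAT
trnQ	tRNA	-	79	138	60			TTG
trnM	tRNA	+	139	208	70			CAT
nad2	PCG	+	208	1233	1026	ATT	TAA
trnW	tRNA	+	1234	1303	70			TCA
trnC	tRNA	-	1303	1369	67			GCA
trnY	tRNA	-	1369	1435	67
cox1	PCG	+	1434	2970	1537	TCG	T(AA)
trnL2	tRNA	+	2970	3038	69			TAA
cox2	PCG	+	3039	3723	685	ATG	T(AA)
trnK	tRNA	+	3723	3795	73			CTT
trnD	tRNA	+	3807	3875	69			GTC
atp8	PCG	+	3876	4037	162	ATT	TAA
atp6	PCG	+	4031	4711	681	ATG	TAA
cox3	PCG	+	4715	5502	788	ATG	TA(A)
trnG	tRNA	+	5503	5569	67			TCC
nad3	PCG	+	5570	5923	354	ATT	TAA
trnR	tRNA	+	5923	5985	63
trnA	tRNA	+	5986	6053	68			TGC
trnN	tRNA	+	6055	6121	67			GTT
trnS1	tRNA	-	6120	6186	67
trnE	tRNA	+	6203	6270	68
trnF	tRNA	-	6268	6334	67			GAA
nad5	PCG	-	6342	8084	1743	GTG	TAA
trnH	tRNA	-	8085	8150	66
nad4	PCG	-	8153	9496	1344	ATG	TAA
nad4L	PCG	-	9490	9786	297	ATG	TAA
trnT	tRNA	+	9789	9853	65			TGT
trnP	tRNA	-	9854	9920	67			TGG
nad6	PCG	+	9920	10443	524	ATA	TAA
cytb	PCG	+	10444	11580	1137	ATG	TAA
trnS2	tRNA	+	11580	11645	66
nad1	PCG	-	11668	12612	945	ATA	TAA
trnL1	tRNA	-	12619	12686	68			TAG
rrnL	rRNA	-	12688	14021	1334
trnV	tRNA	-	14023	14094	72			TAC
rrnS	rRNA	-	14095	14891	797
CR	CR	+	14892	16585	1694
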