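name	category	strand	start	end	size	start_codon	stop_codon	anticodon
trnI	tRNA	+	1	67	67			GAT
trnQ	tRNA	-	70	138	69			TTG
trnM	tRNA	+	188	256	69			CAT
nad2	PCG	+	257	1282	1026	ATT	TAA
trnW	tRNA	+	1283	1352	70			TCA
trnC	tRNA	-	1352	1418	67			GCA
trnY	tRNA	-	1419	1486	68
cox1	PCG	+	1485	3021	1537	TCG	T(AA)
trnL2	tRNA	+	3022	3088	67			TAA
cox2	PCG	+	3090	3774	685	ATG	T(AA)
trnK	tRNA	+	3775	3845	71			CTT
trnD	tRNA	+	3862	3930	69			GTC
atp8	PCG	+	3931	4092	162	ATT	TAA
atp6	PCG	+	4086	4766	681	ATG	TAA
cox3	PCG	+	4770	5557	788	ATG	TA(A)
trnG	tRNA	+	5558	5624	67			TCC
nad3	PCG	+	5649	5977	329	ATT	TA(A)
trnR	tRNA	+	5978	6037	60
trnA	tRNA	+	6042	6110	69			TGC
trnN	tRNA	+	6112	6181	70			GTT
trnS1	tRNA	+	6183	6249	67
trnE	tRNA	+	6262	6327	66
trnF	tRNA	-	6326	6392	67			GAA
nad5	PCG	-	6400	8142	1743	GTG	TAA
trnH	tRNA	-	8143	8208	66
nad4	PCG	-	8214	9557	1344	ATG	TAA
nad4L	PCG	-	9551	9847	297	ATG	TAA
trnT	tRNA	+	9850	9915	66			TGT
trnP	tRNA	-	9916	9982	67			TGG
nad6	PCG	+	9985	10506	522	ATT	TAA
cytb	PCG	+	10510	11644	1135	ATG	T(AA)
trnS2	tRNA	+	11645	11710	66
nad1	PCG	-	11734	12675	942	ATA	TAA
trnL1	tRNA	+	12685	12752	68			TAG
rrnL	rRNA	-	12753	14087	1335
trnV	tRNA	-	14089	14160	72			TAC
rrnS	rRNA	-	14162	14941	780
CR	CR	+	14942	16662	1721
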