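canonical	synonyms
nad1	ND1,NADH1,NADH DEHYDROGENASE SUBUNIT 1,NADH-UBIQUINONE OXIDOREDUCTASE CHAIN 1
nad2	ND2,NADH2,NADH DEHYDROGENASE SUBUNIT 2,NADH-UBIQUINONE OXIDOREDUCTASE CHAIN 2
nad3	ND3,NADH3,NADH DEHYDROGENASE SUBUNIT 3,NADH-UBIQUINONE OXIDOREDUCTASE CHAIN 3
nad4	ND4,NADH4,NADH DEHYDROGENASE SUBUNIT 4,NADH-UBIQUINONE OXIDOREDUCTASE CHAIN 4
nad4L	ND4L,NADH4L,NADH DEHYDROGENASE SUBUNIT 4L,NADH-UBIQUINONE OXIDOREDUCTASE CHAIN 4L
nad5	ND5,NADH5,NADH DEHYDROGENASE SUBUNIT 5,NADH-UBIQUINONE OXIDOREDUCTASE CHAIN 5
nad6	ND6,NADH6,NADH DEHYDROGENASE SUBUNIT 6,NADH-UBIQUINONE OXIDOREDUCTASE CHAIN 6
cox1	COX1,COXI,COI,CO1,CYTOCHROME C OXIDASE SUBUNIT 1,CYTOCHROME C OXIDASE SUBUNIT I,CYTOCHROME OXIDASE SUBUNIT 1,COX-1
cox2	COX2,COXII,COII,CO2,CYTOCHROME C OXIDASE SUBUNIT 2,CYTOCHROME C OXIDASE SUBUNIT II,CYTOCHROME OXIDASE SUBUNIT 2,COX-2
cox3	COX3,COXIII,COIII,CO3,CYTOCHROME C OXIDASE SUBUNIT 3,CYTOCHROME C OXIDASE SUBUNIT III,CYTOCHROME OXIDASE SUBUNIT 3,COX-3
atp6	ATP6,ATPASE6,ATPASE 6,ATP SYNTHASE F0 SUBUNIT 6,ATP SYNTHASE SUBUNIT 6
atp8	ATP8,ATPASE8,ATPASE 8,ATP SYNTHASE F0 SUBUNIT 8,ATP SYNTHASE SUBUNIT 8
cytb	CYTB,COB,CYB,CB,CYTOCHROME B,CYTOCHROME B APOENZYME
rrnS	12S,12S RRNA,12S RIBOSOMAL RNA,RRN12,S-RRNA,SSU,SMALL SUBUNIT RIBOSOMAL RNA,12S-RRNA,RNS
rrnL	16S,16S RRNA,16S RIBOSOMAL RNA,RRN16,L-RRNA,LSU,LARGE SUBUNIT RIBOSOMAL RNA,16S-RRNA,RNL
CR	D-LOOP,CONTROL REGION,AT-RICH REGION,A+T RICH REGION,A+T-RICH REGION,AT RICH REGION,PUTATIVE CONTROL REGION
trnA	TRNA-ALA,TRN-A
trnR	TRNA-ARG,TRN-R
trnN	TRNA-ASN,TRN-N
trnD	TRNA-ASP,TRN-D
trnC	TRNA-CYS,TRN-C
trnE	TRNA-GLU,TRN-E
trnQ	TRNA-GLN,TRN-Q
trnG	TRNA-GLY,TRN-G
trnH	TRNA-HIS,TRN-H
trnI	TRNA-ILE,TRN-I
trnK	TRNA-LYS,TRN-K
trnL	TRNA-LEU,TRN-L
trnL1	TRNA-LEU (CUN),TRNA-LEU(CUN),TRNL1
trnL2	TRNA-LEU (UUR),TRNA-LEU(UUR),TRNL2
trnM	TRNA-MET,TRN-M
trnF	TRNA-PHE,TRN-F
trnP	TRNA-PRO,TRN-P
trnS	TRNA-SER,TRN-S
trnS1	TRNA-SER (AGN),TRNA-SER(AGN),TRNS1
trnS2	TRNA-SER (UCN),TRNA-SER(UCN),TRNS2
trnT	TRNA-THR,TRN-T
trnW	TRNA-TRP,TRN-W
trnY	TRNA-TYR,TRN-Y
trnV	TRNA-VAL,TRN-V
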