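Gene	Strand	Start	End	Length	DNARegion
tRNA-Met	+	1	67	67
ND2	+	68	1028	961
tRNA-Trp	+	1029	1091	63
tRNA-TyrAS	+	1092	1149	58
COI	+	1150	2686	1537
COII	+	2687	3359	673
tRNA-Lys	+	3360	3429	70
tRNA-Asp	+	3430	3491	62
ATP8/6	+	3492	4326	835
COIII	+	4327	5104	778
tRNA-Gly	+	5105	5171	67
ND3	+	5172	5511	340
tRNA-Ala	+	5512	5576	65
Intergenic	+	5577	5578	2
tRNA-Arg	+	5579	5640	62
tRNA-Asn	+	5641	5708	68
Intergenic	+	5709	5712	4
tRNA-Ser	+	5713	5769	57
tRNA-Glu	+	5770	5834	65
R2	+	5825	5987	163	*
HAS1	+	5835	9258	3424
tRNA-Ile	+	9259	9322	64
HAS2	+	9323	12930	3608
tRNA-Thr	+	12931	12991	61
tRNA-ProAS/ND6	+	12992	13503	512
Cytb	+	13504	14585	1082
tRNA-Ser	+	14586	14652	67
tRNA-LeuAS/CR2	+	14653	15023	371
CR2	-	14717	15023	307	*
tRNA-Cys	+	15024	15086	63
Intergenic	+	15087	15094	8
tRNA-Tyr	-	1090	1151	62
LAS1	-	1152	5984	4833
ND1	-	5985	6903	919
tRNA-Leu	-	6904	6964	61
16S rRNA	-	6965	8185	1221
tRNA-Val	-	8186	8247	62
12S rRNA	-	8248	8949	702
CR1	-	8950	9258	309
tRNA-IleAS	-	9259	9323	65
tRNA-Gln	-	9324	9390	67
R1	-	9391	9559	169
tRNA-Phe	-	9560	9620	61
ND5	-	9621	11275	1655
tRNA-His	-	11276	11341	66
ND4/4L	-	11342	12928	1587
tRNA-ThrAS	-	12929	12991	63
tRNA-Pro	-	12992	13055	64
LAS2	-	13056	14654	1599
tRNA-Leu	-	14655	14716	62
LAS3	-	14717	1089	1467
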