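Gene	Strand	From	To	Length	Start	Stop
cox1	+	1	1537	1537	ATG	T
tRNA-LeuUUR	+	1538	1602	65
cox2	+	1603	2266	664	ATA	T
tRNA-LysAAR	+	2267	2334	68
atp8	+	2360	2593	234	ATG	TAG
atp6	+	2583	3233	651	ATG	TAA
tRNA-SerUCN	-	3278	3334	57
tRNA-GluGAR	-	3345	3407	63
tRNA-PheUUY	-	3423	3489	67
nd5	-	3490	5143	1654	ATT	T
tRNA-HisCAY	-	5141	5205	65
nd4	-	5206	6498	1293	ATA	TAA
nd4l	-	6495	6779	285	ATG	TAA
tRNA-ThrACN	+	6781	6858	78
tRNA-ProCCN	-	6847	6908	62
nd6	+	6943	7389	547	ATG	TAA
cytb	+	7388	8524	1137	ATG	TAA
tRNA-SerAGY	+	8520	8583	64
nd1	-	8582	9517	936	ATT	TAA
tRNA-LeuCUN	-	9518	9585	68
rrnL	-	9585	10795	1211
tRNA-ValGUN	-	10796	10863	68
tRNA-AspGAY	-	10867	10938	72
tRNA-GlnCAR	-	10944	11007	64
rrnS	-	11017	11687	671
tRNA-AsnAAY	-	11917	11980	64
tRNA-ArgCGN	-	11981	12049	69
tRNA-AlaGCN	-	12053	12117	65
nd3	-	12123	12476	354	ATG	TAA
tRNA-GlyGGN	-	12478	12540	63
cox3	-	12569	13354	786	ATT	TAG
tRNA-IleAUN	+	14328	14396	65
tRNA-MetAUG	+	14395	14462	68
nd2	+	14478	15431	954	ATC	TAA
tRNA-TrpUGG	+	15430	15497	68
tRNA-TyrUAY	-	15496	15558	63
tRNA-CysUGY	-	15557	15630	74
CR1	+	11688	11916	229
CR2	+	13355	14327	973
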