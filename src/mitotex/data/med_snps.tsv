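Pos	Ref	Alt	Gene_name	Strand	SNP_position_in_gene	Three_base_ref	Three_base_alt	aa_ref	aa_alt
984	G	A	cox1	+	984	ATG	ATA	M	M
1873	G	A	cox2	+	271	GAA	AAA	E	K
5020	C	T	nd5	-	124	GGA	AGA	G	S
7510	C	T	cytb	+	123	GTC	GTT	V	V
14675	G	A	nd2	+	198	ACG	ACA	T	T
14011	A	G	CR region
14090	G	A	CR region
14180	A	G	CR region
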