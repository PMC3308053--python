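gene	pos	ref	call	variant_class	location	zygosity	note
Ipo11	107700899	*	-T/*	deletion	Splice site (intronic)	het
Kif2a	107752127	*	*/-G	deletion	3' UTR	het
Slc38a9	113523874	*	-TT/-TT	deletion	5' UTR	hom
Gzmk	113963370	*	*/+T	insertion	Splice site	het
Pfkp	6604227	*	*/+GG	insertion	Exonic	het	Frameshift leading to truncation of protein in exon 10 (approximately half its length)
Gtpbp4	8984980	*	*/-A	deletion	Splice site (intronic)	het
Pgbd1	21515496	*	-AGGAA/-AGGAA	deletion	Splice site (intronic)	hom
Isca1	21587150	*	*/-GGCTGCGG	deletion	5' UTR	het
Hist1h1c	23831772	*	+TN/+TN	insertion	3' UTR	hom
Hist1h1a	23856249	A	A/C	snv	3' UTR	het
Agtr1a	30473986	*	*/-T	deletion	3' UTR	het
Txndc5	38599758	*	*/-A	deletion	Splice site (intronic)	het
Gm9979	40801514	*	+CACACACACACG/*	insertion	3' UTR	het
Tpmt	47135375	A	A/T	snv	Noncoding (retained intron)	het
Iars	49829191	*	*/-TG	deletion	3' UTR	het
Sema4d	51798481	*	*/+G	insertion	Exonic	het	Frameshift leading to truncation of protein in last exon
Cdhr2	54827830	*	*/+G	insertion	Exonic	het	Frameshift leading to truncation of protein in exon 19 (approximately two-thirds of its length)
Smad5	56824847	*	*/+CACACACACACA	insertion	5' UTR	het
Smad5	56824796	C	C/T	snv	5' UTR	het
Klhl3	58165232	*	-GA/-GA	deletion	Splice site (intronic)	hom
Ptch1	63613020	*	*/+A	insertion	Exonic	het	Frameshift leading to truncation of protein very close to carboxyl terminus
1110018J18Rik	64393367	*	+A/*	insertion	3' UTR	het
Sdha	74460494	T	G/T	snv	3' UTR	het
Spata9	76115351	*	-C/-C	deletion	Exonic	hom	Frameshift leading to incorrect final 15 amino acids and loss of stop codon
Fam81b	76408769	*	+TTA/+TTA	insertion	Exonic	hom	Gain of stop codon leading to truncation of protein after 15 amino acids
Rasa1	85370111	*	+G/+G	insertion	Noncoding (retained intron)	hom
Rasgrf2	92024132	*	-A/-A	deletion	Splice site (intronic)	hom
Pde8b	95822955	*	*/-TAA	deletion	Noncoding (retained intron)	het
Bdp1	100808235	*	*/+A	insertion	Splice site (intronic)	het
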