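gene	chrom	pos	ref	alt	category	aa_change	mut_consensus	mut_genotype	mut_consensus_quality	mut_snp_quality	mut_mapping_quality	mut_read_depth	bg_consensus	bg_genotype	bg_consensus_quality	bg_snp_quality	bg_mapping_quality	bg_read_depth	cap_background	cap_mutant	comment
1700001K19Rik	12	111907080	T	A	nonsynonymous	H:L	A	hom_alt	20	51	58	63	T/A	het	72	134	55	73	Deletion	Deletion	Misalignment around deletion
1700104B16Rik	8	34841236	G	C	nonsynonymous	H:D	G/C	het	76	76	55	54	G	hom_ref	9	0	52	58	G/C	G/C	Incorrect background read with very low consensus score
Acsl3	1	78692680	C	A	stop_gained		A	hom_alt	7	25	49	16	A/C	het	9	9	56	15	C	C	Miscalled in both samples; low consensus and SNP quality
Bcl2l14	6	134377474	T	G	nonsynonymous	N:K	G	hom_alt	3	36	50	64	G/A	het	9	10	60	61	NA	Deletion	Misalignment around deletion; low quality consensus and SNP scores
Btnl7	17	34670007	C	T	nonsynonymous	G:R	C/T	het	6	96	48	30	T	hom_alt	96	141	53	44	C/T	C/T	Background read miscalled as a homozygote
Catsper2	2	121223476	T	C	nonsynonymous	N:D	C	hom_alt	33	33	47	83	T/C	het	15	28	44	86	Deletion	Deletion	Misalignment around deletion
Col6a3	1	92672331	C	G	essential_splice_site		G	hom_alt	30	30	60	16	A	hom_alt	33	33	29	18	NA	Deletion	Misalignment around deletion
Creb3l2	6	37284584	T	C	essential_splice_site		C/T	het	38	38	54	23	T	hom_ref	11	0	56	18	T	T	Mutant read miscalled as a heterozygote
Gm10859	2	5833494	A	G	nonsynonymous	I:V	A/G	het	41	48	56	18	A	hom_ref	39	0	41	17	Deletion	Deletion	Misalignment around deletion
Gm11149	9	49380322	A	C	nonsynonymous	Q:P	C	hom_alt	0	36	54	30	G/C	het	0	23	52	30	Deletion	Deletion	Misalignment around deletion and low quality consensus scores
Gtf3c2	5	31476808	T	C	nonsynonymous	E:G	C/T	het	25	25	49	39	T	hom_ref	33	0	52	30	T	T	Mutant read miscalled as a heterozygote; low consensus and SNP quality
H2-Oa	17	34229420	T	C	nonsynonymous	V:A	C/T	het	3	35	48	86	T	hom_ref	39	0	46	79	Deletion	Deletion	Misalignment around deletion
Ido1	8	25703857	C	T	nonsynonymous	R:K	C/T	het	21	21	50	30	C	hom_ref	13	0	53	39	C	C	Mutant read miscalled as a heterozygote; low consensus and SNP quality
Isl1	13	117098488	T	C	nonsynonymous	Y:C	C/T	het	199	228	60	66	T	hom_ref	223	0	60	65	T	C/T	Confirmed by capillary sequencing
Mdc1	17	35984844	G	T	nonsynonymous	E:D	T	hom_alt	13	39	50	11	G/T	het	21	21	55	11	G	G	Miscalled in both samples; low consensus quality
Olfr424	1	176066876	A	G	essential_splice_site		G/T	het	4	58	58	88	T	hom_alt	6	60	60	88	Insertion	A	Misalignment around insertion; low consensus quality scores
Olfr573-ps1	7	110091057	G	T	nonsynonymous	H:Q	T	hom_alt	21	25	56	82	G/T	het	33	34	56	96	Deletion	Deletion	Misalignment around deletion
Olfr573-ps1	7	110091058	T	A	nonsynonymous	H:L	A	hom_alt	22	45	53	79	T/A	het	8	62	57	96	Deletion	Deletion	Misalignment around deletion
Olfr749	14	51356853	G	T	nonsynonymous	Q:K	G/T	het	36	36	46	81	G	hom_ref	17	0	39	62	Deletion	Deletion	Misalignment around deletion
Rsf1	7	104809403	G	C	nonsynonymous	E:Q	G/C	het	17	22	54	47	G	hom_ref	42	0	55	45	Deletion	Deletion	Misalignment around deletion
Rsf1	7	104809404	A	T	nonsynonymous	E:V	A/T	het	14	22	54	47	A	hom_ref	42	0	55	45	Deletion	Deletion	Misalignment around deletion
Sap30bp	11	115825338	G	A	nonsynonymous	A:T	A/G	het	31	31	55	61	G	hom_ref	40	0	55	52	G	G	Mutant read miscalled as a heterozygote
U1	1	172958261	T	A	essential_splice_site		A/T	het	18	105	51	69	A	hom_alt	26	75	51	58	Deletion	Deletion	Misalignment around deletion
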