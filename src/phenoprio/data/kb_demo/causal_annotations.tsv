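chrom	pos	ref	alt	gene	transcript	hgvs_c	hgvs_p	consequence	total_af	subpop_afs	insilico_scores	curated_flags	notes
13	20763612	A	G	GJB2	NM_004004.6	c.101T>C	p.Met34Thr	missense	0.012	gnomAD_EAS=0.06	REVEL=0.72;ada_score=0.81	functional_damaging;clinvar_pathogenic	synthetic demo annotation; common pathogenic allele kept by curated BA1 exemption
13	20763604	C	T	GJB2	NM_004004.6	c.109G>A	p.Val37Ile	missense	0.02	gnomAD_EAS=0.08	REVEL=0.68;ada_score=0.74	functional_damaging;clinvar_pathogenic	synthetic demo annotation; common pathogenic allele kept by curated BA1 exemption
13	20763477	AC	A	GJB2	NM_004004.6	c.235delC	p.Leu79CysfsTer3	frameshift	.	.	.	lof_mechanism_gene;clinvar_pathogenic	synthetic demo annotation
13	20763413	TAT	T	GJB2	NM_004004.6	c.299_300delAT	p.His100ArgfsTer14	frameshift	.	.	.	lof_mechanism_gene;clinvar_pathogenic	synthetic demo annotation
7	107350577	A	G	SLC26A4	NM_000441.1	c.2168A>G	p.His723Arg	missense	.	.	REVEL=0.93;ada_score=0.97	hotspot_domain;clinvar_pathogenic	synthetic demo annotation
7	107323898	A	G	SLC26A4	NM_000441.1	c.919-2A>G	.	splice_acceptor	.	.	.	lof_mechanism_gene;clinvar_pathogenic	synthetic demo annotation
7	107334926	C	T	SLC26A4	NM_000441.1	c.1229C>T	p.Thr410Met	missense	.	.	REVEL=0.9;ada_score=0.88	hotspot_domain;functional_damaging;clinvar_pathogenic	synthetic demo annotation
2	26695775	C	T	OTOF	NM_001287489.1	c.2521G>A	p.Glu841Lys	missense	.	.	REVEL=0.8;rf_score=0.7	phenotype_specific_match	synthetic demo annotation
2	26684126	C	T	OTOF	NM_001287489.1	c.5816G>A	p.Arg1939Gln	missense	.	.	REVEL=0.95;ada_score=0.91	hotspot_domain;functional_damaging;clinvar_pathogenic	synthetic demo annotation
11	76922298	C	T	MYO7A	NM_000260.4	c.6070C>T	p.Arg2024Ter	stop_gained	.	.	.	lof_mechanism_gene;clinvar_pathogenic	synthetic demo annotation
11	76867061	G	A	MYO7A	NM_000260.4	c.640G>A	p.Gly214Arg	missense	.	.	REVEL=0.92;ada_score=0.9	hotspot_domain;clinvar_pathogenic	synthetic demo annotation
17	18045893	G	A	MYO15A	NM_016239.4	c.4642G>A	p.Gly1548Arg	missense	.	.	REVEL=0.88;rf_score=0.83	hotspot_domain;clinvar_pathogenic	synthetic demo annotation
9	75136717	C	T	TMC1	NM_138691.3	c.100C>T	p.Arg34Ter	stop_gained	.	.	.	lof_mechanism_gene;clinvar_pathogenic	synthetic demo annotation
21	43795836	C	T	TMPRSS3	NM_024022.4	c.916G>A	p.Ala306Thr	missense	.	.	REVEL=0.86;ada_score=0.84	hotspot_domain;functional_damaging;clinvar_pathogenic	synthetic demo annotation
10	73462443	C	T	CDH23	NM_022124.6	c.719C>T	p.Pro240Leu	missense	.	.	REVEL=0.9;ada_score=0.87	hotspot_domain;clinvar_pathogenic	synthetic demo annotation
1	41285562	G	C	KCNQ4	NM_004700.4	c.827G>C	p.Trp276Ser	missense	.	.	REVEL=0.94;rf_score=0.9	hotspot_domain;segregates;clinvar_pathogenic	synthetic demo annotation
4	6303922	C	T	WFS1	NM_006005.3	c.2051C>T	p.Ala684Val	missense	.	.	REVEL=0.91;ada_score=0.89	hotspot_domain;functional_damaging;clinvar_pathogenic	synthetic demo annotation
14	31346651	C	T	COCH	NM_004086.3	c.151C>T	p.Pro51Ser	missense	.	.	REVEL=0.84;ada_score=0.8	hotspot_domain;segregates;clinvar_pathogenic	synthetic demo annotation
11	121052406	C	T	TECTA	NM_005422.4	c.5597C>T	p.Thr1866Met	missense	.	.	REVEL=0.82;rf_score=0.78	hotspot_domain;clinvar_pathogenic	synthetic demo annotation
17	79478310	G	A	ACTG1	NM_001614.5	c.833C>T	p.Thr278Ile	missense	.	.	REVEL=0.89;ada_score=0.85	hotspot_domain;segregates;clinvar_pathogenic	synthetic demo annotation
1	35250398	C	T	GJB3	NM_024009.2	c.538C>T	p.Arg180Ter	stop_gained	.	.	.	lof_mechanism_gene;clinvar_pathogenic	synthetic demo annotation
12	112915523	A	G	PTPN11	NM_002834.3	c.922A>G	p.Asn308Asp	missense	.	.	REVEL=0.96;ada_score=0.93	de_novo_confirmed;hotspot_domain;other_change_same_residue_pathogenic;segregates;clinvar_pathogenic	synthetic demo annotation
12	112910841	A	G	PTPN11	NM_002834.3	c.836A>G	p.Tyr279Cys	missense	.	.	REVEL=0.97;ada_score=0.95	de_novo_confirmed;de_novo_assumed;hotspot_domain;other_change_same_residue_pathogenic;clinvar_pathogenic	synthetic demo annotation
12	112915602	T	A	PTPN11	NM_002834.3	c.1001T>A	p.Leu334Gln	missense	.	.	REVEL=0.6;ada_score=0.7	.	synthetic demo annotation
17	42971757	C	T	EFTUD2	NM_001258353.1	c.271+1G>A	p.Glu91AspfsTer24	splice_donor	.	.	.	lof_mechanism_gene;de_novo_confirmed;functional_damaging;phenotype_specific_match	synthetic demo annotation
X	82763281	C	T	POU3F4	NM_000307.5	c.499C>T	p.Gln167Ter	stop_gained	.	.	.	lof_mechanism_gene;clinvar_pathogenic	synthetic demo annotation
MT	1555	A	G	MT-RNR1	NR_137294.1	m.1555A>G	.	other	.	.	.	functional_damaging;phenotype_specific_match;clinvar_pathogenic	synthetic demo annotation
15	43893860	C	T	STRC	NM_153700.2	c.4701+1G>A	.	splice_donor	.	.	.	lof_mechanism_gene;clinvar_pathogenic	synthetic demo annotation
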