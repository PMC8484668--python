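chrom	pos	ref	alt	assertion	source	filter_exempt
13	20763612	A	G	pathogenic	ClinVar:GJB2:c.101T>C:p.Met34Thr	true
13	20763604	C	T	pathogenic	ClinVar:GJB2:c.109G>A:p.Val37Ile	true
13	20763477	AC	A	pathogenic	ClinVar:GJB2:c.235delC	false
13	20763413	TAT	T	pathogenic	ClinVar:GJB2:c.299_300delAT	false
7	107350577	A	G	likely_pathogenic	ClinVar:SLC26A4:c.2168A>G:p.His723Arg	false
7	107323898	A	G	pathogenic	ClinVar:SLC26A4:c.919-2A>G	false
7	107334926	C	T	pathogenic	ClinVar:SLC26A4:c.1229C>T:p.Thr410Met	false
2	26695775	C	T	likely_pathogenic	ClinVar:OTOF:c.2521G>A:p.Glu841Lys	false
2	26684126	C	T	pathogenic	ClinVar:OTOF:c.5816G>A:p.Arg1939Gln	false
11	76922298	C	T	pathogenic	ClinVar:MYO7A:c.6070C>T:p.Arg2024Ter	false
11	76867061	G	A	pathogenic	ClinVar:MYO7A:c.640G>A:p.Gly214Arg	false
17	18045893	G	A	likely_pathogenic	ClinVar:MYO15A:c.4642G>A:p.Gly1548Arg	false
9	75136717	C	T	pathogenic	ClinVar:TMC1:c.100C>T:p.Arg34Ter	false
21	43795836	C	T	pathogenic	ClinVar:TMPRSS3:c.916G>A:p.Ala306Thr	false
10	73462443	C	T	pathogenic	ClinVar:CDH23:c.719C>T:p.Pro240Leu	false
1	41285562	G	C	likely_pathogenic	ClinVar:KCNQ4:c.827G>C:p.Trp276Ser	false
4	6303922	C	T	pathogenic	ClinVar:WFS1:c.2051C>T:p.Ala684Val	false
14	31346651	C	T	likely_pathogenic	ClinVar:COCH:c.151C>T:p.Pro51Ser	false
11	121052406	C	T	likely_pathogenic	ClinVar:TECTA:c.5597C>T:p.Thr1866Met	false
17	79478310	G	A	likely_pathogenic	ClinVar:ACTG1:c.833C>T:p.Thr278Ile	false
1	35250398	C	T	pathogenic	ClinVar:GJB3:c.538C>T:p.Arg180Ter	false
12	112915523	A	G	pathogenic	ClinVar:PTPN11:c.922A>G:p.Asn308Asp	false
12	112910841	A	G	pathogenic	ClinVar:PTPN11:c.836A>G:p.Tyr279Cys	false
12	112915602	T	A	vus	ClinVar:PTPN11:c.1001T>A:p.Leu334Gln	false
17	42971757	C	T	pathogenic	ClinVar:EFTUD2:c.271+1G>A	false
X	82763281	C	T	pathogenic	ClinVar:POU3F4:c.499C>T:p.Gln167Ter	false
MT	1555	A	G	pathogenic	ClinVar:MT-RNR1:m.1555A>G	false
15	43893860	C	T	pathogenic	ClinVar:STRC:c.4701+1G>A	false
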