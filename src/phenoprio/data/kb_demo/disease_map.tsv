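disease_id	name	gene	inheritance	hpo_terms
DFNB1A	GJB2-related autosomal recessive deafness	GJB2	AR	HP:0008527;HP:0008625;HP:0008619
DFNA3B	GJB3-related autosomal dominant deafness	GJB3	AD	HP:0005101;HP:0001730;HP:0000407
DFNB4	SLC26A4-related deafness with enlarged vestibular aqueduct	SLC26A4	AR	HP:0000407;HP:0011389;HP:0008560;HP:0000853
DFNB9	OTOF-related auditory neuropathy	OTOF	AR	HP:0000404;HP:0008527
NS1	Noonan syndrome 1	PTPN11	AD	HP:0000407;HP:0030148;HP:0001642;HP:0000465;HP:0004322
NSML	Noonan syndrome with multiple lentigines	PTPN11	AD	HP:0001003;HP:0000407;HP:0001642;HP:0000953
MFDGA	Mandibulofacial dysostosis Guion-Almeida type	EFTUD2	AD	HP:0005321;HP:0000410;HP:0001629;HP:0001263
DFNB2	MYO7A-related autosomal recessive deafness	MYO7A	AR	HP:0008527;HP:0001751
USH1B	Usher syndrome type 1B	MYO7A	AR	HP:0008527;HP:0000510;HP:0001751
DFNB3	MYO15A-related autosomal recessive deafness	MYO15A	AR	HP:0008527;HP:0008625
DFNB7	TMC1-related autosomal recessive deafness	TMC1	AR	HP:0008527;HP:0008625
DFNA36	TMC1-related autosomal dominant deafness	TMC1	AD	HP:0001730;HP:0000407
DFNB8	TMPRSS3-related autosomal recessive deafness	TMPRSS3	AR	HP:0000407;HP:0001730
DFNB12	CDH23-related autosomal recessive deafness	CDH23	AR	HP:0008527;HP:0008625
DFNA2A	KCNQ4-related autosomal dominant deafness	KCNQ4	AD	HP:0001730;HP:0005101;HP:0000407
DFNA6	WFS1-related low-frequency deafness	WFS1	AD	HP:0000407;HP:0001730
WFSL	Wolfram-like syndrome	WFS1	AD	HP:0000407;HP:0000648;HP:0000819
DFNA9	COCH-related deafness with vestibular dysfunction	COCH	AD	HP:0001730;HP:0001751;HP:0000407
DFNA8	TECTA-related autosomal dominant deafness	TECTA	AD	HP:0000407
DFNA20	ACTG1-related autosomal dominant deafness	ACTG1	AD	HP:0001730;HP:0000407
DFNX2	POU3F4-related X-linked deafness	POU3F4	XL	HP:0000410;HP:0008527
MTRNR1D	Mitochondrial aminoglycoside-induced deafness	MT-RNR1	MT	HP:0000407;HP:0008625
DFNB16	STRC-related autosomal recessive deafness	STRC	AR	HP:0000407
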