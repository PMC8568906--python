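individual_id	family_id	sex	cohort	is_clinvar	clinvar_accession	condition	build	genomic_text	pos	ref	alt	style	transcript	coding	protein	inheritance	publication	ancestry	technology	prs	same_individual_as	formally_tested_asd
MSSNG00342-003	MSSNG00342	M	MSSNG	0			hg38	g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.A1227Gfs*69	paternal_mosaic	This paper	European	WGS	3.639		yes
MSSNG00342-004	MSSNG00342	F	MSSNG	0			hg38	g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.A1227Gfs*69	paternal_mosaic	This paper	European	WGS	6.336		yes
1-1047-003	1-1047	M	MSSNG	0			hg38	g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.A1227Gfs*69	maternal_mosaic	This paper	European	WGS	-1.167		yes
2-1774-003	2-1774	M	MSSNG	0			hg38	g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.A1227Gfs*69	de_novo	This paper	European	WGS	7.035		yes
7-0572-003	7-0572	M	MSSNG-DB7	0			hg38	g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.A1227Gfs*69	de_novo	This paper	European	WGS	15.606		yes
1505221080	1505221080	M	this_paper	0			hg38	g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.A1227Gfs*69	de_novo	This paper	N/A	Direct Sanger sequencing			yes
HNDS_0130-01	HNDS_0130	F	this_paper	0			hg38	g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dupG	p.A1227Gfs*69	de_novo	This paper	N/A	WES			yes
ASD-2_pt1	ASD-2	M	literature	0									NM_033517.1	c.3679dup		maternal_mosaic	Durand et al.	European	FISH and direct sequencing			yes
ASD-2_pt2	ASD-2	M	literature	0									NM_033517.1	c.3679dup		maternal_mosaic	Durand et al.	N/A	FISH and direct sequencing			yes
S7	S7	F	literature	0			hg19	g.51159940dupG	51159940	G	GG	hgvs_dup	NM_033517.1	c.3679dupG	p.A1227Gfs*69	unknown	De Rubeis et al.	N/A	WES			not_assessed
S8	S8	M	literature	0			hg19	g.51159940dupG	51159940	G	GG	hgvs_dup	NM_033517.1	c.3679dupG	p.A1227Gfs*69	de_novo	De Rubeis et al.	N/A	WES			yes
B1	B1	F	literature	0			hg19	g.51159940dupG	51159940	G	GG	hgvs_dup	NM_033517.1	c.3679dupG	p.A1227Gfs*69	de_novo	De Rubeis et al.	N/A	WES			yes
AU013503	AU013503	F	literature	0			hg19						NM_033517.1	c.3679dupG	p.Ala1227fs	unknown	Zhou et al.	Chinese	Target sequencing			yes
AU035703	AU035703	F	literature	0			hg19						NM_033517.1	c.3679dupG	p.Ala1227fs	de_novo	Zhou et al.	Chinese	Target sequencing			yes
14470.p1	14470	M	SSC	0			hg19	22-51159932-T-TG	51159932	T	TG	vcf_anchored	ENST00000262795.3	c.3719_3720insG	p.Ala1243GlyfsTer6	de_novo	O'Roak et al.; This paper	European	WES; WGS	6.718		yes
ASD-685	ASD-685	M	literature	0									NM_033517	c.3630dupG	p.L1210fs	de_novo	Du et al.	Chinese	WES			yes
G01-GEA-71-HI	G01-GEA-71-HI	F	literature	0			hg19	22:51159932:T:TG	51159932	T	TG	vcf_anchored				de_novo	Satterstrom et al.	N/A	WES			yes
SP0051409	SP0051409	F	literature	0			hg19	22-51159932-T-TG	51159932	T	TG	vcf_anchored	ENST00000262795.3	c.3720dupG	p.L1240fs	de_novo	Feliciano et al.	N/A	WES			yes
Farwell	Farwell	N/A	literature	0									NM_033517.1	c.3679dupG	p.A1227Gfs*69	de_novo	Farwell et al.	American	WES			yes
ClinVar_SCV000850848	ClinVar_SCV000850848	N/A	clinvar	1	SCV000850848	History of Neurodevelopmental Disorder	hg38	Chr22:g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.Ala1227fs	unknown	Ambry Genetics	N/A	Clinical testing			not_assessed
ClinVar_SCV000244220	ClinVar_SCV000244220	N/A	clinvar	1	SCV000244220	Inborn genetic diseases	hg38	Chr22:g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.Ala1227fs	unknown	Ambry Genetics	N/A	Clinical testing			not_assessed
ClinVar_SCV001149930a	ClinVar_SCV001149930a	N/A	clinvar	1	SCV001149930	22q13.3 deletion syndrome	hg38	Chr22:g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.Ala1227fs	de_novo	Institute of Human Genetics, Klinikum rechts der Isar	N/A	Clinical testing			not_assessed
ClinVar_SCV001149930b	ClinVar_SCV001149930b	N/A	clinvar	1	SCV001149930	22q13.3 deletion syndrome	hg38	Chr22:g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.Ala1227fs	de_novo	Institute for Genomic Statistics and Bioinformatics, University Hospital Bonn	N/A	Clinical testing			not_assessed
ClinVar_SCV000329516	ClinVar_SCV000329516	N/A	clinvar	1	SCV000329516	No condition provided	hg38	Chr22:g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.Ala1227fs	unknown	GeneDx	N/A	Clinical testing			not_assessed
ClinVar_SCV001468904	ClinVar_SCV001468904	N/A	clinvar	1	SCV001468904	No condition provided	hg38	Chr22:g.50721512dup	50721512	G	GG	hgvs_dup	NM_033517.1	c.3679dup	p.Ala1227fs	unknown	Laboratoire de Genetique Moleculaire, CHU Bordeaux	N/A	Clinical testing			not_assessed
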