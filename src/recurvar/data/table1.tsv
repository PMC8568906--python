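build	transcript	exon	genomic_text	pos	ref	alt	style	coding	protein	tool	note
hg38	NM_033517.1	21	Chr22:50721512-50721513	50721512	G	GG	hgvs_dup	c.3679dup	p.(Ala1227Glyfs*69)	Alamut Visual v2.15.0	
hg38	NM_001080420.1	22	Chr22:g.50721512dup	50721512	G	GG	hgvs_dup	c.3727dup	p.(Ala1243Glyfs*69)	Alamut Visual v2.15.0	transcript record suppressed by NCBI
hg38	ENST00000262795.5	24	Chr22:g.50721512dup	50721512	G	GG	hgvs_dup	c.3676dup	p.(Ala1226Glyfs*69)	Alamut Visual v2.15.0	
hg38	NM_001372044	22	22-50721503-50721504-T-TG	50721504	T	TG	vcf_anchored	c.3855dupG	p.L1285fs	MSSNG	replaces NM_033517
hg19	NM_033517.1	21	Chr22:51159940-51159941	51159940	G	GG	hgvs_dup	c.3679dup	p.(Ala1227Glyfs*69)	Alamut Visual v2.15.0	
hg19	NM_001080420.1	22	Chr22:g.51159940dup	51159940	G	GG	hgvs_dup	c.3727dup	p.(Ala1243Glyfs*69)	Alamut Visual v2.15.0	
hg19	ENST00000262795.5	24	Chr22:g.51159940dup	51159940	G	GG	hgvs_dup	c.3676dup	p.(Ala1226Glyfs*69)	Alamut Visual v2.15.0	
hg19	NM_033517	21	chr22:51159932-51159932-T-TG	51159932	T	TG	vcf_anchored	c.3630dup	p.L1210fs	VariCarta; GATK	
hg19			chr22:51159933-51159933-G-GG	51159933	G	GG	vcf_anchored			VariCarta	mid-run anchored spelling
hg19	ENST00000262795.3	22	22-5119932-T-TG	51159932	T	TG	vcf_anchored	c.3719_3720insG	p.Ala1243GlyfsTer6	O'Roak et al.	printed coordinate 5119932 lacks a digit; parsed as 51159932
hg19	ENST00000262795.3	22	22-5119932-T-TG	51159932	T	TG	vcf_anchored	c.3720dupG	p.L1240fs	Feliciano et al.	printed coordinate 5119932 lacks a digit; parsed as 51159932
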