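individual_id	family_id	sex	asd	dysmorphia	id_dd	other_medical	psychiatric	neurological	organ_anomalies	language_speech
MSSNG00342-003	MSSNG00342	M	yes	yes	yes	not_assessed	yes	not_assessed	yes	yes
MSSNG00342-004	MSSNG00342	F	yes	yes	yes	not_assessed	yes	not_assessed	not_assessed	yes
1-1047-003	1-1047	M	yes	not_assessed	yes	not_assessed	yes	yes	not_assessed	yes
2-1774-003	2-1774	M	yes	not_assessed	yes	yes	yes	yes	yes	yes
7-0572-003	7-0572	M	yes	not_assessed	yes	yes	yes	not_assessed	not_assessed	yes
1505221080	1505221080	M	yes	not_assessed	yes	not_assessed	yes	yes	not_assessed	not_assessed
ASD-2_pt1	ASD-2	M	yes	yes	yes	not_assessed	not_assessed	yes	not_assessed	yes
ASD-2_pt2	ASD-2	M	yes	yes	yes	not_assessed	not_assessed	yes	not_assessed	yes
S7	S7	F	not_assessed	not_assessed	yes	not_assessed	not_assessed	yes	yes	yes
S8	S8	M	yes	not_assessed	yes	not_assessed	not_assessed	yes	not_assessed	yes
B1	B1	F	yes	yes	yes	yes	yes	yes	yes	yes
AU013503	AU013503	F	yes	not_assessed	yes	not_assessed	not_assessed	not_assessed	not_assessed	yes
AU035703	AU035703	F	yes	not_assessed	yes	yes	yes	yes	not_assessed	yes
14470.p1	14470	M	yes	not_assessed	yes	not_assessed	not_assessed	yes	not_assessed	yes
ASD-685	ASD-685	M	yes	not_assessed	yes	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed
G01-GEA-71-HI	G01-GEA-71-HI	F	yes	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed
SP0051409	SP0051409	F	yes	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed
Farwell	Farwell	N/A	yes	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed	not_assessed
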