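name	start	end	description
ANK	113	346	ankyrin repeats
SH3	470	529	SRC homology 3 domain
PDZ	656	741	PSD-95/Discs large/zona occludens domain
HBS	1311	1323	Homer binding site (proline-rich)
CBS	1469	1497	Cortactin binding site (proline-rich)
SAM	1654	1718	sterile alpha motif domain
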