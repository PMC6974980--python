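# name	recognition	cut_offset_top
XhoI	CTCGAG	1
BamHI	GGATCC	1
PflFI	GACNNNGTC	4
PvuI	CGATCG	4
EcoRI	GAATTC	1
HindIII	AAGCTT	1
SalI	GTCGAC	1
NheI	GCTAGC	1
SpeI	ACTAGT	1
XbaI	TCTAGA	1
PstI	CTGCAG	5
KpnI	GGTACC	5
SacI	GAGCTC	5
SmaI	CCCGGG	3
EcoRV	GATATC	3
NdeI	CATATG	2
NcoI	CCATGG	1
BglII	AGATCT	1
ClaI	ATCGAT	2
MfeI	CAATTG	1
AflII	CTTAAG	1
AgeI	ACCGGT	1
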