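label	orthogroup	rayt_accession	rayt_strain	iupac
PF1	I	YP_002873491	P. fluorescens SBW25	GTGGGAGGGGGCTTGCCCCCGAT
PF2	I	n.a.		GTGGGAGGGGGCTTGCTCCCGAT
PF3	II	n.a.		GTAGGAGCYGGCTTGCCRGCGAA
PF4	II	EJM82571	P. sp. GM60	GTAGGAGCCGGCTTGCTGGCGAT
PF5	III	EJN28792	P. sp. GM80	GTGGYGAGGGGATTTATCCCCG
PF6	III	n.a.		GTGGCGAGGGGGCTTGTCCCCCG
PF7	III	EJM60273	P. sp. GM49	GTGGCGAGGGGGCTTGCCCCCG
PF8	IV	EIK66912	P. fluorescens Q8r1-96	GTGGGAGCGAGCTTGCTCGCGAT
PF9	IV	EKA23398	P. fluorescens BBc6R8	GTGGGAGCGGGCTTGCTCGCGAA
PF10	IV	EJM47370	P. sp. GM33	GTGGGAGCGAGCYTGCTCGCGAA
PF11	IV	n.a.		GTAGGAGTGAGCCTGCTCGCGAT
PF12	IV	YP_006323329	P. fluorescens A506	GTGGGAGCTGGCTTGCCTGCGAT
PF13	IV	n.a.		GTGGGAGCGGGCTTGCCCGCGAT
PF14	IV	ZP_10622153	P. sp. GM78	GTGGGAGCTGGCTTGCCAGCGAT
PF15	IV	EJM57603	P. sp. GM41 (2012)	GTGGGAGCCAGCCTGCTGGCGAT
PF16	IV	EJM16763	P. sp. GM21	GTGGGAGCTAGCCTGCTAGCGAT
PF17	NO	YP_002871781	P. fluorescens SBW25	GTGGCGAGGGAGCTTGCTCCCGCT
PF18	NO	ZP_10436910	P. extremaustralis 14-3	GTAGGAGCGAGCYYGCTCGCGA
PF19	NO	YP_004351241	P. brassicacearum NFM421	GTRGGAGCAAGGCTTGCCCGCGAT
PF20	NO	EJM39110	P. sp. GM33	GTAGGAGCTGCCGAAGGCTGCGAT
PF21	NO	EIM18788	P. chlororaphis O6	GTAGGAGCGAGGCTTGCCCGCGA
PF22	NO	YP_002873800	P. fluorescens SBW25	GTRGTGAGCGGGCTTGCCCCGCGCT
SM1	I	YP_001970973	S. maltophilia K279a	GGTGGGTGCCGACCGTTGGTCGGCAC
SM2	I	YP_002708831	S. sp. SKA14	GGTGGGTGCCAACCTTGGTTGGCAC
SM3	I	YP_006183766	S. maltophilia D457	GTAGWTGCCAACCTTGGTTGGCA
SM4	II	YP_002706198	S. sp. SKA14	GTRGATCCACGCCATGCGTGGAT
SM5	II	n.a.		GTAGAGCCACCCCATGGGTGGCT
SM6	III	n.a.		GGTAGAGTCGACTGTTAGTCGACT
SM7	III	n.a.		GTAGMGCCGGGYTCTRCCCGGCK
SM8	NO	YP_001972572	S. maltophilia K279a	GGTAGTGCCGGCCGCTGGCCGGCA
SM9	NO	YP_002030358	S. maltophilia R551-3	TGTAGAGCCGAGCCCATGCTCGGCT
SM10	NO	YP_002029847	S. maltophilia R551-3	GGTAGCGCCGGGCCATGCCCGGCG
SM11	NO	YP_004793143	S. maltophilia JV3	TGTAGAGTCGAGCCATGCTCGACT
SM12	NO	n.a.		GTAGAGTCGAGCTTGCTCGACT
SM13	NO	n.a.		GTAGAGCCGACCGTTGGTCGGCT
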