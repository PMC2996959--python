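mirna_id	mirna_seq	target_id	site_seq	reported_mismatches
ctr-miRn2	UUAAGAUUGAGUUACCAUCAU	24238	AUGAUGGUAACUCAAUCUUAA	0
ctr-miRn3	AUAAUGAUGUCUGUGAUGCCU	20080	AGGCAUCACAGACAUCAUUAU	0
ctr-miRn4	UAGACCGCAAGAGACUAGCAA	17900	UUGCUAGUCUCUUGCGAUCUA	1
ctr-miRn10	UUUCUUCAUGAGAGCUGGCCA	42150	UGGCCAGCUCUCAUGAAGAAA	0
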