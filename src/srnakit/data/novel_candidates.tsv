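id	sequence	precursor_accession	au_percent	arm	lm	lp	reads	star
ctr-miRn1	AGAGAUCAAGUUGCAGAGCAA	EX447269	69.9	5'	21	83	41	Yes
ctr-miRn2	UUAAGAUUGAGUUACCAUCAU	EY823533	55.8	5'	21	86	5	Yes
ctr-miRn3	AUAAUGAUGUCUGUGAUGCCU	EY674266	55.4	3'	21	81	14	Yes
ctr-miRn4	UAGACCGCAAGAGACUAGCAA	EY845571	54.9	3'	21	82	37	Yes
ctr-miRn5	UGAAGGUCCGAGGUCGAGGUU	EY669005	66.3	3'	21	83	10	No
ctr-miRn6	UAAAUGUUGAGAGGAUUUGGC	DC890743	67.1	3'	21	76	5	No
ctr-miRn7	UGAGCGGCUGAAAAGAGGGAGAAA	DC893595	61.8	5'	24	89	6	No
ctr-miRn8	UAGGUGUAGAGAAGCACGAGA	CV712896	64.7	3'	21	85	10	No
ctr-miRn9	UUAGGGAUAUAACAGUUGAAU	CX297999	71.3	5'	21	73	110	No
ctr-miRn10	UUUCUUCAUGAGAGCUGGCCA	DT214737	47.1	5'	21	87	268	Yes
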