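family_id	locus	discrepancy
2	UC	NEITHER_PARENT
4	UC	MISSING_PARENTAL
8	DBB	EXTRA_ALLELE
12	UC	MISSING_PARENTAL
12	DAB	EXTRA_ALLELE
16	DAB	EXTRA_ALLELE
20	UC	MISSING_PARENTAL
20	DBB	MISSING_PARENTAL
25	UC	MISSING_PARENTAL
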