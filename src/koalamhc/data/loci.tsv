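locus	class	fwd_primer	rev_primer	amplicon_bp	genome_copies	coamplified_paralog
UA	I	ACCCCTGACCCTGCCGTGTC	CACCGCCTTCGCTCTGGTTGA	313	1	UB
UC	I	AAGGTCTCCAATGTTTCCGACTCA	TCTCGCGCTAAGGCCATACC	397	1
DAB	II	ATGCCCCAAAGCACTTCAC	CGCACTRAGAAGGGCTCA	271	3
DBB	II	AGGGACATCCCAGAGGATTTCG	TCTTCTGTCCACCGCGAAGG	282	3
DCB	II	GGTGAGGTCTGAGTGTCACA	CATTCACTATGGACCTTGCAGT	200	1
DMB	II	CATGTGGAGAGTGGCTGTATG	GTCCTTTGGGTCAACGCTC	266	1
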