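# Packaged fixtures

Hand-curated once from the published genotype tables of the captive
Lone Pine koala study population; guarded by checksum in the test suite.

- `loci.tsv` — the six MHC gene targets (class I UA, UC; class II DAB,
  DBB, DCB, DMB) with exon-2 PCR primers, amplicon sizes and genome copy
  numbers. The UA primer pair co-amplifies the paralogous UB gene, so the
  UA target is treated as a pooled UA+UB target throughout.
- `family_profiles.tsv` — per-individual called allele sets for the 36
  family units (18 dam–sire–joey trios, families 1–18; 18 single-parent
  pairs, families 19–36). Class I allele labels keep their two-field form
  (e.g. `01:01`); class II labels are bare numbers (e.g. `03`).
- `pedigree.tsv` — family structure; empty dam/sire cells mean the parent
  was not genotyped.
- `expected_discrepancies.tsv` — the nine family×locus cells flagged as
  Mendelian-incongruent in the published tables (their italicised
  entries), with the discrepancy class each one represents.

Normalisation applied during curation (typesetting artifacts in the
source tables): allele fields are zero-padded to two digits (`5:02` →
`05:02`), and a stray `:` used as a list separator is read as `;`.
Repeated individuals (a koala appearing in several families, e.g. Byron,
Mooloolah) are deduplicated by name after an exact-consistency check.
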