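# Methods

This note documents the models, rules and numerical choices behind
`koalamhc`, and what the simulator does and does not emulate.

## Targets and reference database

Six PCR targets amplify the exon-2 (receptor-binding groove) region:
class I *UA* (313 bp) and *UC* (397 bp); class II *DAB* (271 bp), *DBB*
(282 bp), *DCB* (200 bp) and *DMB* (266 bp), amplicon sizes including
primers. *DAB* and *DBB* are present as three gene copies in the
genome, the others as single copies. The *UA* primers co-amplify the
paralogous *UB* gene; because UA and UB alleles are too similar to
segregate by gene of origin, the pipeline models *UA* as one pooled
UA+UB target with a ceiling of 2 × 2 = 4 distinct alleles per koala.
Other targets cap at 2 × copy-number alleles.

Reference alleles are stored primer-trimmed (amplicon interior only) so
merged, trimmed reads compare to them directly. FASTA headers follow
`>LOCUS*LABEL`, with class I labels keeping their two-field form
(`UC*01:01`) and class II labels bare numbers (`DBB*03`). Novel
sequences get provisional per-locus labels `novel-001`, `novel-002`, …
— a namespace that cannot collide with published names. Degenerate
IUPAC bases are permitted in primers (the *DAB* reverse primer carries
an R) and match their expansion set during primer search.

## Read processing

- **Locus assignment.** A pair is assigned to the unique locus whose
  forward primer matches a prefix of the forward mate and reverse
  primer a prefix of the reverse mate, each with at most 2 substitutions
  (no indels; IUPAC-aware). Zero or multiple matching loci leave the
  pair unassigned. The tolerance of 2 on 18–24 bp primers accepts
  realistic error rates while keeping the six primer sets mutually
  distinguishable; substitutions-only keeps trim coordinates exact.
- **Trimming and culling.** Each mate loses its leading primer bases
  and is then truncated to the amplicon interior length taken from the
  locus table, which removes any 3′ read-through into the opposite
  primer's reverse complement (and adaptor beyond it) deterministically.
  Pairs with a trimmed mate strictly shorter than 150 bp are culled;
  exactly 150 bp survives. All coordinates are 0-based half-open, and
  the interior is always reported on the forward-primer strand.
- **Merging.** The reverse mate is reverse-complemented and every start
  offset within the forward mate is scored. Admissible offsets need
  overlap ≥ 10 bp and mismatch fraction ≤ 0.25 (common defaults for
  overlap-merging tools; the defaults are explicit package choices).
  The longest admissible overlap wins; ties break on fewest mismatches,
  then smallest offset — a total order, so output is deterministic. At
  conflicting positions the higher-quality base is taken, with quality
  ties resolved to the forward base. That tie rule makes merging of a
  *conflicting, equal-quality* column asymmetric under mate swap;
  error-free pairs merge strand-symmetrically.

## Genotype calling

Matching is exact-sequence lookup first; otherwise global pairwise
alignment (edit distance via edlib) against every allele at the locus,
with identity 1 − d/max(len). The best allele is accepted at identity
≥ 0.98 — roughly "within a handful of errors of one allele" on these
interiors; two alleles tied at the best identity leave the read
ambiguous, and ambiguous reads never increment allele counts, avoiding
double counting between near-identical alleles. Unmatched and ambiguous
reads accumulate by exact sequence.

An allele is called present when its reads are **strictly more than
10%** of the target's total for that koala — the calling rule of the
original workflow, applied with a sharp boundary (exactly 10% is never
called). A locus with no reads is `NO_DATA`, distinct from an empty
set, so pedigree checks skip it rather than score it.

Novel-allele discovery applies the same >10% rule to exact-duplicate
clusters of unmatched reads, plus an absolute floor of 10 copies to
guard tiny-depth pathologies. Candidates are registered into the
(running) reference and the koala's reads re-tallied; the loop stops
when a round adds nothing, capped at 3 rounds to preclude oscillation.
Each round is deterministic given the read multiset. Because errors
leave only a fraction of a true allele's reads as exact duplicates, a
withheld allele near the 10% fraction may escape discovery; at the
fractions single-copy carriers produce (≥ 50%) discovery is reliable.

## Pedigree congruence

The published account states the principle (offspring inherit an allele
from each parent and carry nothing foreign); the operational rule here
was chosen to realize it with unphased allele sets:

- **Trio:** congruent iff joey ⊆ dam ∪ sire AND joey∩dam ≠ ∅ AND
  joey∩sire ≠ ∅. Discrepancy classes, in precedence order:
  `NEITHER_PARENT` (no allele shared with either parent),
  `MISSING_PARENTAL` (no allele shared with one parent),
  `EXTRA_ALLELE` (an allele absent from both parents, otherwise
  sharing with each). One class per family×locus.
- **Pair** (one genotyped parent): congruent iff the joey shares at
  least one allele with that parent; joey alleles the parent lacks are
  attributed to the unknown parent and never flagged.

Multi-copy loci use the same set rule — true per-copy inheritance is
unverifiable without phasing. Percentages are rounded half-up to whole
percent. On the packaged 36-family tables this rule reproduces exactly
the nine flagged cells of the published tables (and no others); that
reproduction is a frozen golden test.

## Population statistics

Profiles are encoded as binary presence vectors over the sorted union
of observed (locus, allele) pairs. On symmetric binary attributes with
equal weights, Gower's similarity coefficient reduces to simple
matching, so the clustering distance is the fraction of differing
columns — an alternative encoding (one categorical variable per locus)
was considered and set aside because the binary encoding handles
variable allele counts per locus cleanly. Complete-linkage clustering
is implemented directly (naive O(n³)) so tie-breaking is specified:
minimum cluster distance, ties to the lowest cluster-id pair. Heights
are non-decreasing (complete linkage is monotone); output uses the
standard linkage-matrix layout plus Newick export with branch lengths
derived from merge heights.

The two-sided Fisher exact p sums hypergeometric probabilities of all
margin-fixed tables whose probability does not exceed the observed
one, with 1e-7 relative slack in the comparison; counts ≤ 500 use exact
integer binomials, larger tables the scipy hypergeometric pmf. The χ²
test is the Pearson statistic with df = (rows−1)(cols−1). Carrier
prevalences are reported rounded half-up. Raw p-values are reported;
no multiple-testing correction is applied, as none is part of the
method. The published haplotype-heterogeneity χ² is not reproducible —
its input table is not recoverable — so the χ² machinery is covered by
oracle and property tests instead.

## Simulator

The generator emulates the sequencing design: per koala, each target
receives 500 read pairs (2×250 bp, fixed Q35) allocated multinomially
with uniform weights over the koala's chromosomes; substitution errors
are injected independently per base at 0.2% by default. Allele pools
are random interiors of exactly the target's interior length with
pairwise Hamming distance ≥ 5 (rejection sampling, bounded retries),
six alleles per locus by default — within the observed per-locus range
of 3–10. Founders draw alleles per chromosome per gene copy from the
configured frequencies (uniform by default); joeys inherit, per gene
copy, one uniformly chosen chromosome from each parent, so simulated
trios are Mendelian by construction. Pair families simulate both
parents but expose only one in the pedigree. The pooled UA+UB target is
two independent single-copy genes sharing one read label. Degenerate
primer positions are realized to a fixed concrete base. Output FASTQ is
byte-reproducible under a fixed seed (gzip written with fixed mtime).

Not emulated: PCR amplification skew between alleles, chimeras/PCR
artifacts, indel errors, and learned quality profiles. Passing tests
therefore demonstrate correctness of the processing and calling logic
under the stated error model, not robustness to amplification bias —
the >10% threshold's behaviour under strong skew is untested against
real data.

## Problem sizes and defaults

The end-to-end validation runs five independent cohorts of 20 sequenced
koalas (4 trios + 4 pairs) × 6 targets at depth 500 and 0.2% error —
600 individual×locus comparisons — and separately withholds one carried
single-copy allele from the reference to verify verbatim novel-sequence
recovery for every carrier. Key defaults: primer mismatches 2; merge
overlap ≥ 10 at mismatch density ≤ 0.25; match identity ≥ 0.98; calling
threshold 0.10 (strict); novel floor 10 copies; novel iteration cap 3.

## Known limitations

- The calling threshold treats each koala×target independently; very
  uneven amplification between co-amplified alleles could drop a true
  allele below 10% (seen in the published families as rare
  missing-parental cases) or a systematic artifact could exceed it.
- The pair rule cannot detect a joey allele absent from both true
  parents when only one parent is genotyped.
- Allele assignment ignores reads tied between two references rather
  than fractionally assigning them; at equal identity no principled
  split exists without haplotype priors.
- Published reference allele sequences are not distributed with the
  package; reference-dependent behaviour is exercised with simulated
  alleles.
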