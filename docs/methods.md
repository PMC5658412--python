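# Methods

## Model

Let *R* be a reference sequence and consider an indel event with pattern
*P* (the pure inserted or deleted bases, no anchor base) whose first
affected base sits at position *q*. Applying the event yields the
alternate sequence *R′*. Two indels of the same type are *equivalent*
when they yield the identical alternate sequence. Within a repetitive
context, the set of equivalent placements of one indel has two structural
properties the package relies on:

1. every equivalent placement carries a cyclic rotation of *P*, and
2. the placements occupy a contiguous interval of positions.

Both follow from the factorization of the repeated context: if two
equivalent placements are separated by a spacer *S*, then *P·S = S·P′*
forces *P′* to be a rotation of *P* (splitting on whether |S| is
smaller than, equal to, or larger than |P| and recursing in the last
case). The package does not manipulate that proof symbolically; instead
`sequences.exhaustive_equivalents` enumerates *all* patterns of the
seed's length at all positions on small inputs and the test suite
confirms that only rotations ever appear, while `bruteforce_region`
asserts contiguity on every call.

## Coordinate conventions

Positions are 1-based; ranges are inclusive on both ends. An insertion's
position is the position its first inserted base occupies in the
alternate — the pattern goes immediately before the reference base
currently at that position, and `end + 1` is a legal append position. A
deletion's position is its first deleted base. These conventions make
published range starts sit one past the VCF anchor base, and make a
homopolymer run of *n* bases admit exactly *n − L + 1* deletion
placements and *n + 1* insertion placements for events of length *L* —
both closed forms are asserted in tests.

## The extension algorithm

`ups.compute_ups` walks the placement outward in both directions, one
position per step, rotating the pattern as it goes:

* insertion, right shift *q → q+1*: legal iff `ref[q] == pattern[0]`;
  the pattern rotates left.
* insertion, left shift *q → q−1*: legal iff `ref[q−1] == pattern[-1]`;
  rotate right.
* deletion, right shift: legal iff `ref[q] == ref[q+L]`; rotate left.
* deletion, left shift: legal iff `ref[q−1] == pattern[-1]`; rotate
  right.

The boundary base advances with every accepted shift. The walk stops at
the first mismatch or when it runs out of contig (clamped, not an
error). `N` and any non-ACGT base never match, so regions stop at
assembly gaps rather than extending through them. The canonical pattern
reported is the rotation in force at the *leftmost* placement, so
equivalent indels serialize to identical strings regardless of which
representation was stored. Because equivalence regions are contiguous,
single-step extension is exhaustive; the oracle-equivalence test checks
interval and canonical pattern against brute-force enumeration on 10,000
randomized repeat-rich instances, and a placement-invariance test
re-anchors each seed at every position of its own region and requires
the identical coordinate — the property that makes key equality a
correct equivalence test.

## From VCF records to primitive events

Vertical decomposition splits a multiallelic record into one record per
ALT. Trimming removes the longest shared prefix (advancing the
position), then the longest shared suffix; the order is fixed for
determinism and does not affect the final coordinate, since
canonicalization happens in the extension step anyway. What remains
classifies as a pure insertion, pure deletion, SNV, no-op, or a complex
variant.

Complex variants (MNPs and clumped indels) are decomposed horizontally
by Needleman–Wunsch global alignment of the trimmed alleles. Scores are
match +2, mismatch −1, linear gap −2; they are configurable, but the
defaults are the contract the decomposition tests pin down. Among
co-optimal alignments the traceback deterministically prefers
substitutions placed leftmost with gap runs after them (implemented by
aligning the reversed alleles under a diagonal > up > left preference
and reversing the result). This choice reproduces the canonical
decompositions of `ATAA→AG` (T→G substitution, then deletion of `AA`)
and `AAAAA→AG` (A→G at the second base, then deletion of `AAA`), and for
homopolymer contexts it puts the indel part in the same equivalence
region as the plain-indel spellings of the mutation, which is what makes
cross-representation matching work. Mismatch columns become SNVs;
maximal gap runs become one indel each; applying the emitted primitives
left to right reconstructs ALT from REF exactly (property-tested).

Each decomposed primitive indel is annotated independently against the
*original* reference, not the post-substitution sequence: a deletion
byproduct extends through the full repeat run regardless of its sibling
SNV. SNVs never receive a UPS-coordinate; by default they are emitted as
their own unannotated UVCF rows for losslessness (`emit_snv_rows`).

## UVCF and file handling

UVCF appends one column, named `UPS-COORDINATE` on the `#CHROM` line,
holding the serialized coordinate or `.`. The serialized grammar is
`±PATTERN[lower-upper]` with an ASCII hyphen; the parser additionally
accepts spaces and en/em-dash or minus-sign separators as they appear in
print. Because the extra column is not legal VCF, reading and writing is
line-based: mandatory columns are parsed, QUAL/FILTER/INFO/FORMAT/sample
columns are carried verbatim (and copied unchanged onto split rows), and
headers round-trip byte-identically for files the package wrote. FASTA
access goes through pyfaidx with uppercase folding of soft-masked bases.
Records with symbolic alleles (`<DEL>`, breakends, `*`) or with `N`
inside the event region pass through unannotated. REF-allele mismatches
against the reference are handled per the `validate` mode: `warn` (emit
the row unannotated), `skip` (drop it), or `fail` (raise).

## Redundancy and comparison

Grouping uses the full key — contig, sign, canonical pattern, range —
never the range alone: an insertion and a deletion can share a range in
one repeat tract while meaning different mutations. The redundancy ratio
is (Σ group sizes − number of groups) / total annotated indels, i.e. the
fraction of records that are copies. Filtering keeps per group the
member with the smallest (position, id) — the tie-break is a package
choice made for determinism — and preserves input order; grouping the
filtered output is empty by construction (tested as a fixed point).
Call-set comparison uses distinct-key semantics (a key present twice in
one set counts once) and reports per-set totals, common and unique key
counts, and the Jaccard index. The classical baseline — same type, same
literal pattern, positions within ±5 bp, greedy one-to-one
earliest-first matching — is provided as `distance_match` for
methodological comparison; it misses pairs separated by more than the
window and pairs stored as different rotations.

## Synthetic fixtures

`fixtures.generate_fixture` emulates the situation the annotation
exists for: a reference assembled from random spacers (10–20 bp) and
tandem-repeat tracts of period 1–6 with enough copies that each planted
group's region can host the requested number of representations
(default 3, range 2–5; default 4 groups plus 3 singleton indels).
Planted representations are drawn from the *actual* equivalence region
computed on the assembled reference and cross-checked against the
brute-force oracle before emission, and singleton indels are retried
until their keys collide with nothing planted, so the truth partition
is exact by construction rather than by expectation. Output is a pure
function of the seed (byte-identical FASTA/VCF/truth for equal specs).

What the fixtures do not emulate: sequencing or alignment error, real
genomic repeat-length distributions, haplotype structure, and genotype
columns. Passing the planted-recovery tests therefore demonstrates
correctness of the equivalence computation and the key machinery, not
calling accuracy on real data.

## Numerical and scale choices

All computations are exact integer/string operations; there are no
tolerances. The randomized test sizes — 10,000 oracle-agreement
instances on references up to 60 bp with patterns up to 5 bp, 400
full-enumeration instances within the guard (pattern ≤ 3, reference
≤ 15), homopolymer runs up to 30, 100 fixture seeds, 1,000 random
decomposition pairs — were chosen as the point where a further order of
magnitude stopped changing what the tests could reveal; each suite runs
in seconds.

## Known limitations

* Equivalence is per single indel. Combinations of neighbouring indels
  whose joint haplotype matches another variant's are out of scope, so
  a deletion equivalent to the union of two nearby deletions is not
  detected.
* No reverse-strand reasoning; coordinates are forward-strand only.
* BCF and full VCF-spec validation are out of scope; INFO/FORMAT fields
  are carried, never interpreted.
* One printed reference row in the source material for the multiallelic
  deletion example (`GTG→GTGCA` as `+CA[7552658-7552658]`) is
  inconsistent with any trimming convention; the package reports
  `+CA[7552660-7552660]` for that allele, per its stated conventions.
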