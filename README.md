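# upsvcf

Equivalence-range (universal positioning) coordinates for indels in VCF
files: annotation, redundancy detection, filtering, and call-set
comparison.

## The problem

An insertion or deletion inside a repetitive stretch of the genome can be
written at many reference positions that all produce the same mutated
sequence. Inserting `TC` into `GTCTA` after the first base gives
`GTCTCTA` — but so does inserting `CT` one base later, and two more
spellings besides. Variant databases and callers routinely store the same
mutation under different coordinates, and position-based comparison
(strict equality, left normalization to a single position, or a ±k bp
window) misses part of the equivalence.

## The idea

Equivalent placements of one indel carry cyclic rotations of a single
pattern and occupy a *contiguous* interval of reference positions. So
instead of one normalized position, each indel is annotated with its
whole region of equivalence, written as a **UPS-coordinate**

```
±PATTERN[lower-upper]
```

where the sign is the indel type (`+` insertion, `-` deletion),
`PATTERN` is the rotation valid at the leftmost placement, and
`[lower, upper]` is the inclusive range of first-affected-base positions
admitting an equivalent representation. The range is found by sliding the
placement outward one base at a time: a shift is legal exactly when the
reference base crossing the event boundary matches the current rotation's
edge symbol (insertion right-shift from *q*: `ref[q] == pattern[0]`,
rotate left; deletion right-shift: `ref[q] == ref[q + L]`; the left side
mirrors this), stopping at the first mismatch or the contig edge. Two
records denote the same mutation exactly when their UPS-coordinates are
equal as strings.

Around the core computation the package provides the standard workflow:
multiallelic records are split vertically (one row per ALT), alleles are
trimmed, complex variants (MNPs, clumped indels) are decomposed
horizontally into primitive SNVs and indels by Needleman–Wunsch global
alignment (match +2, mismatch −1, gap −2; deterministic traceback), and
each primitive indel is annotated against the original reference. The
output is a **UVCF** file — the input VCF with one extra
`UPS-COORDINATE` column — from which redundant-group listing, filtering
and call-set comparison are plain key operations.

## Worked example

```python
from upsvcf import Placement, ReferenceSequence, bruteforce_region, compute_ups

ref = ReferenceSequence("toy", 1, "GTCTA")
seed = Placement(position=2, pattern="TC", kind="insertion")
sorted((p.position, p.pattern) for p in bruteforce_region(ref, seed))
# [(2, 'TC'), (3, 'CT'), (4, 'TC'), (5, 'CT')]
print(compute_ups(seed, ref))
# +TC[2-5]
```

Four distinct placements produce the alternate `GTCTCTA`; the coordinate
`+TC[2-5]` names all of them at once. End-to-end, on a dinucleotide
repeat (`examples/02_annotate_uvcf.py`):

```
#CHROM  POS  ID   REF  ALT  QUAL  FILTER  INFO  UPS-COORDINATE
chr1    9    rsA  T    TTG  .     .       .     +TG[10-19]
chr1    10   rsB  T    TGT  .     .       .     +TG[10-19]
```

The two rows spell the same TG insertion at neighbouring anchors with
different rotations; the shared key `+TG[10-19]` exposes the redundancy,
which `upsvcf redundant-list` turns into a group and `upsvcf filter`
collapses to one representative. See `examples/` for runnable scripts
covering each capability, including the comparison against the classical
±5 bp same-pattern baseline, which misses equivalent pairs separated by
more than the window or stored as different rotations.

## Command line

```
upsvcf annotate ref.fa in.vcf out.uvcf --hd=true   # VCF -> UVCF
upsvcf redundant-list in.uvcf groups.txt           # groups + redundancy ratio
upsvcf filter in.uvcf out.uvcf                     # one representative per group
upsvcf compare a.uvcf b.uvcf report.txt            # key-overlap statistics
upsvcf fixture --seed 1 out_prefix                 # synthetic test data
```

The redundancy ratio reported by `redundant-list` is
(total members of redundant groups − number of groups) / total annotated
indels — the fraction of records that are redundant copies of another
record.

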