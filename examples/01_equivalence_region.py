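"""Where else could this insertion go?

Inserting TC into GTCTA after the first base gives GTCTCTA — but so does
inserting CT one base later, and so on across the short TC/CT repeat.
This script enumerates every equivalent placement by brute force and then
computes the same answer with the extension algorithm, printed as a
UPS-coordinate.
"""

from upsvcf import Placement, ReferenceSequence, apply_indel, bruteforce_region, compute_ups

ref = ReferenceSequence("toy", 1, "GTCTA")
seed = Placement(position=2, pattern="TC", kind="insertion")

print(f"reference        : {ref.bases}")
print(f"alternate        : {apply_indel(ref, seed)}")
print("equivalent placements (position, pattern):")
for p in sorted(bruteforce_region(ref, seed)):
    print(f"  {p.position}  {p.pattern}")

ups = compute_ups(seed, ref)
print(f"UPS-coordinate   : {ups}")
print()
print("All four placements produce the same alternate sequence; the")
print("coordinate +TC[2-5] names the mutation by its whole region of")
print("equivalence, so any of the four VCF spellings maps to one key.")
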