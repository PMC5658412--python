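"""Plant equivalent indels, recover them as redundant groups, filter.

The fixture generator builds a repeat-rich reference and a VCF in which
each planted group consists of several distinct spellings of one indel.
Annotation plus UPS-key grouping recovers exactly the planted partition;
filtering keeps one representative per group, after which no redundancy
remains.
"""

import tempfile
from pathlib import Path

from upsvcf import FixtureSpec, annotate, generate_fixture, read_uvcf
from upsvcf.redundancy import filter_redundant, group_redundant, redundant_ratio

work = Path(tempfile.mkdtemp(prefix="upsvcf_demo_"))
fix = generate_fixture(FixtureSpec(seed=42, groups=3, representations_per_group=3, singletons=2))
(work / "fix.fa").write_text(fix.fasta)
(work / "fix.vcf").write_text(fix.vcf)

annotate(work / "fix.vcf", work / "fix.fa", work / "fix.uvcf")
rows = list(read_uvcf(work / "fix.uvcf"))
groups = group_redundant(rows)

print("planted truth :", [list(g) for g in fix.truth])
print("recovered     :", [[m for m, _ in g.members] for g in groups])
ratio = redundant_ratio(sum(1 for r in rows if r.ups is not None), groups)
print(f"redundant indel ratio: {ratio:.3f}")
# 3 groups of 3 -> 6 of 11 annotated records are redundant copies

kept = filter_redundant(rows, groups)
print(f"after filtering: {len(kept)} of {len(rows)} rows remain, "
      f"{len(group_redundant(kept))} groups left")
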