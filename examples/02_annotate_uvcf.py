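"""Annotate a small VCF against a FASTA and print the UVCF.

Two dbSNP-style records spell the same TG insertion into a TG-dinucleotide
repeat at neighbouring positions.  After annotation both rows carry the
identical UPS-coordinate in the appended UPS-COORDINATE column, which is
what makes the redundancy visible.
"""

import tempfile
from pathlib import Path

from upsvcf import annotate

work = Path(tempfile.mkdtemp(prefix="upsvcf_demo_"))
fasta = work / "mini.fa"
vcf = work / "mini.vcf"

fasta.write_text(">chr1\nACCTGAGCTTGTGTGTGTTCCAAG\n")
vcf.write_text(
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    "chr1\t9\trsA\tT\tTTG\t.\t.\t.\n"
    "chr1\t10\trsB\tT\tTGT\t.\t.\t.\n"
)

out = work / "mini.uvcf"
n = annotate(vcf, fasta, out)
print(f"wrote {n} rows to {out}\n")
print(out.read_text())
print("Both rows end in +TG[10-19]: the insertion of TG is equivalent at")
print("every start position from 10 through 19, so rsA and rsB are the")
print("same mutation stored twice.")
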