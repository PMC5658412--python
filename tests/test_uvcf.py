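"""FASTA/VCF reading, the annotation pipeline, and UVCF round trips."""

from pathlib import Path

import pytest

from upsvcf.errors import MissingContigError, VcfFormatError
from upsvcf.sequences import ReferenceSequence
from upsvcf.ups import serialize_ups
from upsvcf.uvcf import (
    annotate,
    annotate_records,
    load_reference,
    read_uvcf,
    read_vcf,
    read_vcf_header,
    write_uvcf,
)
from upsvcf.variants import VcfVariantRecord


def write(tmp_path: Path, name: str, text: str) -> Path:
    p = tmp_path / name
    p.write_text(text)
    return p


VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


# -- load_reference ----------------------------------------------------------


def test_load_reference_single_contig(tmp_path):
    p = write(tmp_path, "r.fa", ">chr1\nGTCTA\n")
    ref = load_reference(p)
    assert (ref.contig, ref.offset, ref.bases) == ("chr1", 1, "GTCTA")


def test_load_reference_uppercases_softmask(tmp_path):
    p = write(tmp_path, "r.fa", ">chr1\ngtcta\n")
    assert load_reference(p).bases == "GTCTA"


def test_load_reference_multi_contig(tmp_path):
    p = write(tmp_path, "r.fa", ">a\nACGT\n>b\nTTTT\n")
    assert load_reference(p, "b").bases == "TTTT"
    with pytest.raises(MissingContigError):
        load_reference(p, "missing")
    with pytest.raises(MissingContigError):
        load_reference(p)  # ambiguous without a contig name


# -- read_vcf ----------------------------------------------------------------


def test_read_vcf_basic(tmp_path):
    p = write(
        tmp_path,
        "v.vcf",
        VCF_HEADER
        + "1\t10009638\trs34748242\tT\tTTG\t.\t.\t.\n"
        + "1\t7552657\trs376707888\tGTG\tG,GTGCA\t.\t.\t.\n"
        + "1\t99\tmono\tA\t.\t.\t.\t.\n",
    )
    recs = list(read_vcf(p))
    assert recs[0].alt_alleles == ("TTG",)
    assert recs[1].alt_alleles == ("G", "GTGCA")
    assert recs[2].alt_alleles == ()
    assert recs[0].passthrough == (".", ".", ".")
    assert read_vcf_header(p) == VCF_HEADER.rstrip("\n").split("\n")


def test_read_vcf_malformed(tmp_path):
    p = write(tmp_path, "v.vcf", VCF_HEADER + "1\tnotanint\tx\tA\tT\n1\t5\tok\tA\tT\n")
    with pytest.raises(VcfFormatError):
        list(read_vcf(p))
    recs = list(read_vcf(p, on_error="skip"))
    assert [r.id for r in recs] == ["ok"]


def test_read_vcf_gzip(tmp_path):
    import gzip

    p = tmp_path / "v.vcf.gz"
    with gzip.open(p, "wt") as fh:
        fh.write(VCF_HEADER + "1\t5\tx\tA\tAT\t.\t.\t.\n")
    assert [r.id for r in read_vcf(p)] == ["x"]


# -- annotation pipeline -----------------------------------------------------


def test_annotate_equivalent_pair(table3):
    """The two printed TG-insertion records receive the identical coordinate."""
    ref, records, expected = table3
    rows = list(annotate_records(records, ref))
    assert [serialize_ups(r.ups) for r in rows] == [expected, expected]
    assert [r.pos for r in rows] == [10009638, 10009639]  # original columns kept


def test_annotate_multiallelic_rows(table5):
    ref, multi, partner, expected = table5
    rows = list(annotate_records([multi, partner], ref))
    assert len(rows) == 4
    assert [serialize_ups(r.ups) for r in rows[:3]] == expected
    assert serialize_ups(rows[3].ups) == expected[0]  # partner joins the first


def test_annotate_complex_with_and_without_hd(table8):
    ref, records, expected = table8
    rows = list(annotate_records(records, ref, hd=True))
    # plain deletion row, then SNV byproduct row (unannotated) + indel row
    assert serialize_ups(rows[0].ups) == expected
    annotated = [r for r in rows[1:] if r.ups is not None]
    unannotated = [r for r in rows[1:] if r.ups is None]
    assert len(annotated) == 1 and len(unannotated) == 1
    assert serialize_ups(annotated[0].ups) == expected

    rows_off = list(annotate_records(records, ref, hd=False))
    assert rows_off[1].ups is None  # complex record passes through untouched
    rows_no_snv = list(annotate_records(records, ref, emit_snv_rows=False))
    assert len(rows_no_snv) == 2


def test_annotate_snv_and_noop_rows():
    ref = ReferenceSequence("1", 1, "ACGTACGT")
    records = [
        VcfVariantRecord("1", 3, "snv", "G", ("T",)),
        VcfVariantRecord("1", 2, "noop", "CG", ("CG",)),
        VcfVariantRecord("1", 4, "sym", "T", ("<DEL>",)),
    ]
    rows = list(annotate_records(records, ref))
    assert [r.ups for r in rows] == [None, None, None]


@pytest.mark.parametrize("mode,n_rows", [("warn", 1), ("skip", 0)])
def test_annotate_ref_mismatch_modes(mode, n_rows):
    ref = ReferenceSequence("1", 1, "ACGTACGT")
    bad = [VcfVariantRecord("1", 2, "bad", "GG", ("G",))]
    rows = list(annotate_records(bad, ref, validate=mode))
    assert len(rows) == n_rows and all(r.ups is None for r in rows)


def test_annotate_ref_mismatch_fail():
    from upsvcf.errors import ReferenceMismatchError

    ref = ReferenceSequence("1", 1, "ACGTACGT")
    bad = [VcfVariantRecord("1", 2, "bad", "GG", ("G",))]
    with pytest.raises(ReferenceMismatchError):
        list(annotate_records(bad, ref, validate="fail"))


# -- files: annotate / write / read ------------------------------------------


@pytest.fixture
def mini_files(tmp_path):
    # T TGTGTGTGT T context as in the dinucleotide example, at offset 1
    fa = write(tmp_path, "m.fa", ">1\nACCTGAGCTTGTGTGTGTTCCAAG\n")
    vcf = write(
        tmp_path,
        "m.vcf",
        VCF_HEADER + "1\t9\trsA\tT\tTTG\t.\t.\t.\n1\t10\trsB\tT\tTGT\t.\t.\t.\n",
    )
    return fa, vcf, tmp_path


def test_annotate_file_end_to_end(mini_files):
    fa, vcf, tmp = mini_files
    out = tmp / "m.uvcf"
    n = annotate(vcf, fa, out)
    assert n == 2
    lines = out.read_text().splitlines()
    assert lines[1].endswith("\tUPS-COORDINATE")
    rows = list(read_uvcf(out))
    assert serialize_ups(rows[0].ups) == serialize_ups(rows[1].ups) == "+TG[10-19]"


def test_uvcf_round_trip_byte_identical(mini_files):
    fa, vcf, tmp = mini_files
    out1, out2 = tmp / "a.uvcf", tmp / "b.uvcf"
    annotate(vcf, fa, out1)
    write_uvcf(out2, read_uvcf(out1), read_vcf_header(vcf))
    assert out1.read_bytes() == out2.read_bytes()


def test_annotation_idempotence(mini_files):
    """Re-annotating the VCF columns of a UVCF reproduces the UPS strings."""
    fa, vcf, tmp = mini_files
    out = tmp / "m.uvcf"
    annotate(vcf, fa, out)
    again = list(
        annotate_records(
            (
                VcfVariantRecord(r.contig, r.pos, r.id, r.ref_allele, (r.alt_allele,), r.passthrough)
                for r in read_uvcf(out)
            ),
            load_reference(fa),
        )
    )
    assert [serialize_ups(r.ups) for r in again] == [
        serialize_ups(r.ups) for r in read_uvcf(out)
    ]


def test_row_conservation(mini_files, tmp_path):
    """Row count equals ALT alleles expanded by decomposition, never fewer
    than the input data lines."""
    fa = write(tmp_path, "c.fa", ">1\nACCTGAGCTTGTGTGTGTTCCAAG\n")
    vcf = write(
        tmp_path,
        "c.vcf",
        VCF_HEADER
        + "1\t9\tm\tT\tTTG,TGT\t.\t.\t.\n"  # 2 alts -> 2 rows
        + "1\t3\tcx\tCTGA\tCG\t.\t.\t.\n"  # complex -> two primitive rows
        + "1\t5\tmono\tG\t.\t.\t.\t.\n",  # 1 row
    )
    out = tmp_path / "c.uvcf"
    assert annotate(vcf, fa, out) == 5
    assert sum(1 for _ in read_uvcf(out)) == 5


def test_read_uvcf_rejects_bad_annotation(tmp_path):
    p = write(
        tmp_path,
        "bad.uvcf",
        "#CHROM\tPOS\tID\tREF\tALT\tUPS-COORDINATE\n1\t5\tx\tA\tAT\tnot-a-ups\n",
    )
    with pytest.raises(VcfFormatError):
        list(read_uvcf(p))
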