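"""Rotations, alternate-sequence construction and the equivalence oracles."""

import random

import pytest
from hypothesis import given, strategies as st

from upsvcf.errors import (
    BoundsError,
    InvalidPatternError,
    ReferenceMismatchError,
    ScaleLimitError,
)
from upsvcf.sequences import (
    Placement,
    ReferenceSequence,
    apply_indel,
    bruteforce_region,
    exhaustive_equivalents,
    rotations,
)


@pytest.mark.parametrize(
    "pattern,direction,expected",
    [
        ("ATCG", "left", ["TCGA", "CGAT", "GATC"]),
        ("ATCG", "right", ["GATC", "CGAT", "TCGA"]),
        ("A", "left", []),
        ("AAA", "left", ["AAA", "AAA"]),
    ],
)
def test_rotations(pattern, direction, expected):
    assert rotations(pattern, direction) == expected


def test_rotations_rejects_bad_patterns():
    with pytest.raises(InvalidPatternError):
        rotations("")
    with pytest.raises(InvalidPatternError):
        rotations("ANT")


@pytest.mark.parametrize(
    "bases,placement,expected",
    [
        ("GTCTA", Placement(2, "TC", "insertion"), "GTCTCTA"),
        ("ACTGTTGTG", Placement(3, "TGT", "deletion"), "ACTGTG"),
        ("ACGT", Placement(1, "ACGT", "deletion"), ""),
        ("ACGT", Placement(5, "T", "insertion"), "ACGTT"),  # append position
    ],
)
def test_apply_indel(bases, placement, expected):
    assert apply_indel(ReferenceSequence("c", 1, bases), placement) == expected


def test_apply_indel_error_contracts():
    ref = ReferenceSequence("c", 1, "ACGT")
    with pytest.raises(ReferenceMismatchError):
        apply_indel(ref, Placement(2, "GG", "deletion"))
    with pytest.raises(BoundsError):
        apply_indel(ref, Placement(6, "A", "insertion"))
    with pytest.raises(BoundsError):
        apply_indel(ref, Placement(4, "TT", "deletion"))


def test_bruteforce_region_dinucleotide(gtcta):
    reg = bruteforce_region(gtcta, Placement(2, "TC", "insertion"))
    assert {(p.position, p.pattern) for p in reg} == {
        (2, "TC"), (3, "CT"), (4, "TC"), (5, "CT")
    }


def test_bruteforce_region_singleton():
    ref = ReferenceSequence("c", 1, "ACGT")
    reg = bruteforce_region(ref, Placement(2, "C", "deletion"))
    assert {(p.position, p.pattern) for p in reg} == {(2, "C")}


def test_bruteforce_region_homopolymer_run():
    # T + G*8 + A: inserting one G admits 9 placements, run start to run end + 1
    ref = ReferenceSequence("1", 150917623, "T" + "G" * 8 + "A")
    reg = bruteforce_region(ref, Placement(150917624, "G", "insertion"))
    assert sorted(p.position for p in reg) == list(range(150917624, 150917633))
    assert {p.pattern for p in reg} == {"G"}


def test_exhaustive_matches_bruteforce(gtcta):
    seed = Placement(2, "TC", "insertion")
    assert exhaustive_equivalents(gtcta, seed) == bruteforce_region(gtcta, seed)


def test_exhaustive_homopolymer_deletion():
    ref = ReferenceSequence("c", 1, "AAAA")
    reg = exhaustive_equivalents(ref, Placement(1, "A", "deletion"))
    assert {(p.position, p.pattern) for p in reg} == {(i, "A") for i in (1, 2, 3, 4)}


def test_exhaustive_append_equivalence():
    # appending T after the final T equals inserting T before it
    ref = ReferenceSequence("c", 1, "ACGT")
    reg = exhaustive_equivalents(ref, Placement(5, "T", "insertion"))
    assert {(p.position, p.pattern) for p in reg} == {(4, "T"), (5, "T")}


def test_exhaustive_guard():
    with pytest.raises(ScaleLimitError):
        exhaustive_equivalents(
            ReferenceSequence("c", 1, "A" * 16), Placement(1, "A", "insertion")
        )
    with pytest.raises(ScaleLimitError):
        exhaustive_equivalents(
            ReferenceSequence("c", 1, "ACGTACGT"), Placement(1, "ACGT", "insertion")
        )


# -- randomized repeat-rich cases -------------------------------------------


def random_case(rng: random.Random):
    """A repeat-rich reference plus a valid seed placement."""
    unit = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 5)))
    copies = rng.randint(2, 8)
    left = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 12)))
    right = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 12)))
    bases = (left + unit * copies + right)[:60]
    ref = ReferenceSequence("c", rng.randint(1, 10_000), bases)
    kind = rng.choice(["insertion", "deletion"])
    plen = rng.randint(1, 5)
    if kind == "deletion":
        if len(bases) < plen:
            plen = len(bases)
        pos = rng.randint(ref.offset, ref.end - plen + 1)
        pattern = ref.slice(pos, pos + plen - 1)
    else:
        pos = rng.randint(ref.offset, ref.end + 1)
        if rng.random() < 0.6:
            pattern = (unit * 5)[:plen]  # repeat-aligned, long regions
        else:
            pattern = "".join(rng.choice("ACGT") for _ in range(plen))
    return ref, Placement(pos, pattern, kind)


@given(st.integers(0, 10_000))
def test_region_contiguity_and_rotation_closure(case_seed):
    """Equivalent placements occupy a contiguous interval and carry only
    rotations of the seed pattern."""
    ref, seed = random_case(random.Random(case_seed))
    region = bruteforce_region(ref, seed)  # contiguity asserted inside
    assert seed in region
    allowed = set([seed.pattern] + rotations(seed.pattern))
    assert {p.pattern for p in region} <= allowed
    target = apply_indel(ref, seed)
    assert all(apply_indel(ref, p) == target for p in region)


@given(st.integers(0, 10_000))
def test_exhaustive_confirms_rotation_only(case_seed):
    """Within the combinatorial guard, full pattern enumeration finds exactly
    the rotation-restricted region: no non-rotation pattern is equivalent."""
    rng = random.Random(case_seed)
    ref, seed = random_case(rng)
    if len(seed.pattern) > 3 or len(ref) > 15:
        ref = ReferenceSequence(ref.contig, 1, ref.bases[:12] or "ACGT")
        plen = min(len(seed.pattern), 3)
        if seed.kind == "deletion":
            pos = rng.randint(1, len(ref) - plen + 1)
            seed = Placement(pos, ref.slice(pos, pos + plen - 1), "deletion")
        else:
            seed = Placement(rng.randint(1, len(ref) + 1), seed.pattern[:plen], "insertion")
    assert exhaustive_equivalents(ref, seed) == bruteforce_region(ref, seed)


@given(st.integers(2, 30), st.integers(1, 5), st.sampled_from("ACGT"))
def test_homopolymer_closed_forms(n, length, base):
    """A run of n identical bases yields n - L + 1 deletion placements and
    n + 1 insertion placements for whole-run-base events of length L."""
    flank = {"A": "C", "C": "G", "G": "T", "T": "A"}[base]
    ref = ReferenceSequence("c", 1, flank + base * n + flank)
    if length <= n:
        dels = bruteforce_region(ref, Placement(2, base * length, "deletion"))
        assert len(dels) == n - length + 1
    ins = bruteforce_region(ref, Placement(2, base * length, "insertion"))
    assert len(ins) == n + 1
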