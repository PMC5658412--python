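"""Shared fixtures.

The `table*` fixtures reconstruct minimal reference contexts around
published dbSNP/COSMIC indels from the facts the records themselves pin
down (REF alleles fix bases at their positions; the known equivalence
ranges fix the repeat tracts; flanking bases are chosen to terminate the
repeats).  They are synthetic stand-ins for GRCh37 windows, adequate
because the equivalence computation only ever reads the local context.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from upsvcf.sequences import ReferenceSequence
from upsvcf.variants import VcfVariantRecord

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture
def gtcta():
    """Reference of the worked insertion example: GTCTA, offset 1."""
    return ReferenceSequence("chr", 1, "GTCTA")


@pytest.fixture
def intro_ref():
    """Printed 21-bp window AGG(AAAG)x4 AG anchored at 100285630."""
    return ReferenceSequence("chr1", 100285630, "AGGAAAGAAAGAAAGAAAGAG")


@pytest.fixture
def table3():
    """TG-dinucleotide repeat context around chr1:10009638 (synthetic).

    Pinned facts: REF base T at 10009638 and 10009639; insertions of TG
    are equivalent over [10009639, 10009648], so the repeat tract is
    TGTGTGTGT at 10009639-10009647 with a non-extending base at 10009648.
    """
    ref = ReferenceSequence("1", 10009630, "ACCTGAGC" + "T" + "TGTGTGTGT" + "T" + "CCAAG")
    records = [
        VcfVariantRecord("1", 10009638, "rs34748242", "T", ("TTG",), (".", ".")),
        VcfVariantRecord("1", 10009639, "rs59148039", "T", ("TGT",), (".", ".")),
    ]
    expected = "+TG[10009639-10009648]"
    return ref, records, expected


@pytest.fixture
def table5():
    """AATGG-pentamer repeat context around chr1:724188 (synthetic).

    Pinned facts: T at 724137 (REF of rs374587598), equivalence range
    [724138, 724189] for whole-unit insertions => tract (AATGG)x10 + A at
    724138-724188; 724189 chosen as C so the ragged third allele is a
    singleton.
    """
    ref = ReferenceSequence(
        "1", 724130, "GCCTCAG" + "T" + "AATGG" * 10 + "A" + "C" + "TTACG"
    )
    multi = VcfVariantRecord(
        "1", 724188, "rs60022176", "A",
        ("AATGGA", "AATGGAATGGAATGGA", "AATGGAATGGG"), (".", "."),
    )
    partner = VcfVariantRecord("1", 724137, "rs374587598", "T", ("TAATGG",), (".", "."))
    expected = [
        "+AATGG[724138-724189]",
        "+AATGGAATGGAATGG[724138-724189]",
        "+ATGGAATGGG[724189-724189]",
    ]
    return ref, multi, partner, expected


@pytest.fixture
def table6():
    """GT context around chr1:7552657 (synthetic).

    Pinned: C at 7552656 (REF of rs139294420), then GTG at 7552657-7552659;
    7552660 chosen G to terminate both the GT-deletion region and the CA
    insertion.
    """
    ref = ReferenceSequence("1", 7552650, "ATCTGA" + "C" + "GTG" + "G" + "ATCCA")
    multi = VcfVariantRecord("1", 7552657, "rs376707888", "GTG", ("G", "GTGCA"), (".", "."))
    partner = VcfVariantRecord("1", 7552656, "rs139294420", "CGT", ("C",), (".", "."))
    expected_deletion = "-GT[7552657-7552658]"
    return ref, multi, partner, expected_deletion


@pytest.fixture
def table8():
    """A-homopolymer context around chr1:2273131 (synthetic).

    Pinned: G at 2273131 (REF anchor of rs369694942); the AAA deletion is
    equivalent over [2273132, 2273147], so the run is A x 18 at
    2273132-2273149 with a non-A base after.
    """
    ref = ReferenceSequence("1", 2273120, "CTGATCCGTAC" + "G" + "A" * 18 + "G" + "CCTGA")
    records = [
        VcfVariantRecord("1", 2273131, "rs369694942", "GAAA", ("G",), (".", ".")),
        VcfVariantRecord("1", 2273140, "rs373243812", "AAAAA", ("AG",), (".", ".")),
    ]
    expected = "-AAA[2273132-2273147]"
    return ref, records, expected


@pytest.fixture
def table10():
    """G-homopolymer context around chr1:150917623 (synthetic): T + G x 8 + A."""
    ref = ReferenceSequence("1", 150917615, "CATCAGTC" + "T" + "G" * 8 + "A" + "CCTGA")
    records = [
        VcfVariantRecord("1", 150917623, "COSM5068028", "TG", ("TGG",), (".", ".")),
        VcfVariantRecord("1", 150917623, "COSM3732389", "T", ("TG",), (".", ".")),
        VcfVariantRecord("1", 150917623, "COSM3685916", "TG", ("T",), (".", ".")),
        VcfVariantRecord("1", 150917624, "COSM5348791", "G", ("GG",), (".", ".")),
    ]
    expected_insertion = "+G[150917624-150917632]"
    expected_deletion = "-G[150917624-150917631]"
    return ref, records, expected_insertion, expected_deletion
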