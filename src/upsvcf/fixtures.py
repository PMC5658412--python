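"""Deterministic synthetic fixtures: repeat-rich references with planted
groups of equivalent indel representations.

The generator emulates the situation the annotation exists for: tandem
repeats (period 1-6) in which one indel admits many placements.  Each
planted group consists of several VCF records that are distinct
placements/rotations of one indel inside one repeat tract; the placements
are drawn from the actual equivalence region computed on the assembled
reference and cross-checked against the brute-force oracle, so the truth
partition is exact by construction.  Everything is a pure function of the
seed: the same spec yields byte-identical FASTA/VCF/truth output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import NamedTuple

from upsvcf.errors import FixtureSizingError
from upsvcf.sequences import Placement, ReferenceSequence, bruteforce_region, rotate
from upsvcf.ups import compute_ups

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture."""

    seed: int
    groups: int = 4
    representations_per_group: int = 3  # 2..5
    singletons: int = 3
    contig: str = "fix1"
    contig_length: int | None = None  # optional cap / pad target
    tracts: tuple[tuple[int, int], ...] | None = None  # (period, copies) per group
    indel_units: tuple[int, int] = (1, 2)  # units inserted/deleted per event
    spacer_range: tuple[int, int] = (10, 20)

    def __post_init__(self) -> None:
        if self.groups < 0 or self.singletons < 0:
            raise FixtureSizingError("counts must be nonnegative")
        if not (2 <= self.representations_per_group <= 5) and self.groups:
            raise FixtureSizingError("representations_per_group must be in 2..5")


class Fixture(NamedTuple):
    fasta: str
    vcf: str
    truth: tuple[tuple[str, ...], ...]  # intended partition: ids per group


class _Plant(NamedTuple):
    pos: int  # VCF anchor position
    vid: str
    ref: str
    alt: str


def _random_unit(rng: random.Random, period: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(period))


def _spacer(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _vcf_record(ref: ReferenceSequence, placement: Placement, vid: str) -> _Plant:
    anchor = placement.position - 1
    base = ref.base(anchor)
    if placement.kind == "insertion":
        return _Plant(anchor, vid, base, base + placement.pattern)
    return _Plant(anchor, vid, base + placement.pattern, base)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build (FASTA text, VCF text, truth partition) from a spec.

    Raises :class:`FixtureSizingError` when the requested tracts cannot fit
    inside ``contig_length``.
    """
    rng = random.Random(spec.seed)
    reps = spec.representations_per_group

    # choose tracts: one per planted group, wide enough to host `reps`
    # distinct placements of a whole-unit indel
    tracts = list(spec.tracts) if spec.tracts is not None else []
    while len(tracts) < spec.groups:
        period = rng.randint(1, 6)
        min_copies = max(2, -(-(reps + 1) // period) + 1)  # region width >= reps
        tracts.append((period, rng.randint(min_copies, max(min_copies, 10))))

    # assemble the reference: spacer, tract, spacer, tract, ...
    parts: list[str] = [_spacer(rng, rng.randint(*spec.spacer_range))]
    tract_at: list[tuple[int, int, str]] = []  # (start pos, copies, unit)
    cursor = 1 + len(parts[0])
    for period, copies in tracts[: spec.groups]:
        unit = _random_unit(rng, period)
        tract_at.append((cursor, copies, unit))
        block = unit * copies
        parts.append(block)
        cursor += len(block)
        sp = _spacer(rng, rng.randint(*spec.spacer_range))
        parts.append(sp)
        cursor += len(sp)
    bases = "".join(parts)
    if spec.contig_length is not None:
        if len(bases) > spec.contig_length:
            raise FixtureSizingError(
                f"assembled fixture needs {len(bases)} bases, cap is {spec.contig_length}"
            )
        bases += _spacer(rng, spec.contig_length - len(bases))
    ref = ReferenceSequence(spec.contig, 1, bases)

    plants: list[_Plant] = []
    truth: list[tuple[str, ...]] = []
    used_keys: set = set()

    for g, (start, copies, unit) in enumerate(tract_at):
        n_units = rng.randint(*spec.indel_units)
        kind = rng.choice(["insertion", "deletion"])
        if kind == "deletion":
            n_units = min(n_units, copies - 1) or 1
        pattern = unit * n_units
        seed_placement = Placement(start, pattern, kind)
        ups = compute_ups(seed_placement, ref)
        width = ups.upper - ups.lower + 1
        assert width >= reps, "tract sizing guarantees enough placements"
        # oracle check: planted representations really are equivalent
        oracle = bruteforce_region(ref, seed_placement)
        assert {p.position for p in oracle} == set(range(ups.lower, ups.upper + 1))

        by_pos = {p.position: p for p in oracle}
        positions = sorted(rng.sample(range(ups.lower, ups.upper + 1), reps))
        ids = []
        for r, q in enumerate(positions):
            vid = f"grp{g}_rep{r}"
            plants.append(_vcf_record(ref, by_pos[q], vid))
            ids.append(vid)
        truth.append(tuple(ids))
        used_keys.add((ups.contig, ups.sign, ups.pattern, ups.lower, ups.upper))

    # singleton indels in spacer territory, retried until their equivalence
    # key collides with nothing already planted
    spacer_positions = sorted(
        set(range(2, len(bases)))  # anchor needs pos-1 >= 1
        - {
            q
            for start, copies, unit in tract_at
            for q in range(max(2, start - 6), start + copies * len(unit) + 6)
        }
    )
    n_single = 0
    attempts = 0
    while n_single < spec.singletons and attempts < 200 * (spec.singletons + 1):
        attempts += 1
        q = rng.choice(spacer_positions)
        kind = rng.choice(["insertion", "deletion"])
        length = rng.randint(1, 3)
        if kind == "deletion":
            if q + length - 1 > len(bases):
                continue
            pattern = ref.slice(q, q + length - 1)
        else:
            pattern = "".join(rng.choice(_BASES) for _ in range(length))
        placement = Placement(q, pattern, kind)
        ups = compute_ups(placement, ref)
        key = (ups.contig, ups.sign, ups.pattern, ups.lower, ups.upper)
        if key in used_keys:
            continue
        used_keys.add(key)
        plants.append(_vcf_record(ref, placement, f"sng{n_single}"))
        n_single += 1
    if n_single < spec.singletons:
        raise FixtureSizingError("could not place requested singleton indels")

    plants.sort(key=lambda p: (p.pos, p.vid))
    fasta_lines = [f">{spec.contig}"]
    fasta_lines += [bases[i : i + 60] for i in range(0, len(bases), 60)]
    vcf_lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={spec.contig},length={len(bases)}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    vcf_lines += [
        f"{spec.contig}\t{p.pos}\t{p.vid}\t{p.ref}\t{p.alt}\t.\t.\t." for p in plants
    ]
    return Fixture(
        "\n".join(fasta_lines) + "\n",
        "\n".join(vcf_lines) + "\n",
        tuple(truth),
    )


def truth_text(fixture: Fixture) -> str:
    """Render the intended partition, one group per line, ids comma-joined."""
    return "\n".join(",".join(g) for g in fixture.truth) + ("\n" if fixture.truth else "")
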