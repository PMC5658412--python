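"""Reference-sequence model, cyclic permutations, and the equivalence oracle.

Two indels of the same type and length are *equivalent* when applying them
to the reference yields the identical alternate sequence.  Inside a
repetitive region every equivalent placement carries a cyclic rotation of
one pattern, and the placements occupy a contiguous interval of reference
positions (the region of equivalence).  This module provides the domain
types and a brute-force oracle that finds the region by direct enumeration;
the production algorithm in :mod:`upsvcf.ups` is validated against it.

Coordinate conventions (used everywhere in the package):

* positions are 1-based and ranges are inclusive on both ends;
* an insertion's position is the position of the *first inserted base* in
  the alternate sequence, i.e. the pattern is inserted immediately before
  the reference base currently at that position; ``end + 1`` is a legal
  append position;
* a deletion's position is the first deleted base.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Literal

from upsvcf.errors import (
    BoundsError,
    InvalidPatternError,
    ReferenceMismatchError,
    ScaleLimitError,
)

IndelKind = Literal["insertion", "deletion"]

_ACGT = frozenset("ACGT")


def _check_pattern(pattern: str) -> None:
    if not pattern:
        raise InvalidPatternError("pattern must be nonempty")
    if not _ACGT.issuperset(pattern):
        raise InvalidPatternError(f"pattern {pattern!r} contains non-ACGT characters")


@dataclass(frozen=True)
class ReferenceSequence:
    """A contiguous stretch of reference bases with a genomic anchor.

    Parameters
    ----------
    contig:
        Chromosome / contig name.
    offset:
        1-based genomic coordinate of the first stored base.
    bases:
        Bases over ``{A, C, G, T, N}``; lowercase (soft-masked) input is
        uppercased on construction.
    """

    contig: str
    offset: int
    bases: str

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise BoundsError(f"offset must be >= 1, got {self.offset}")
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        """Genomic position of the last stored base."""
        return self.offset + len(self.bases) - 1

    def contains(self, position: int) -> bool:
        return self.offset <= position <= self.end

    def base(self, position: int) -> str:
        """Base at a 1-based genomic position."""
        if not self.contains(position):
            raise BoundsError(
                f"position {position} outside [{self.offset}, {self.end}] on {self.contig}"
            )
        return self.bases[position - self.offset]

    def slice(self, start: int, end: int) -> str:
        """Bases in the inclusive genomic interval [start, end]."""
        if start > end:
            return ""
        if not (self.contains(start) and self.contains(end)):
            raise BoundsError(
                f"interval [{start}, {end}] outside [{self.offset}, {self.end}] on {self.contig}"
            )
        return self.bases[start - self.offset : end - self.offset + 1]


@dataclass(frozen=True, order=True)
class Placement:
    """One concrete representation of an indel on the reference."""

    position: int
    pattern: str
    kind: IndelKind = field(default="insertion")

    def __post_init__(self) -> None:
        _check_pattern(self.pattern)
        if self.position < 1:
            raise BoundsError(f"position must be >= 1, got {self.position}")


def rotate(pattern: str, direction: Literal["left", "right"] = "left") -> str:
    """Single-step cyclic rotation of a pattern."""
    _check_pattern(pattern)
    if direction == "left":
        return pattern[1:] + pattern[0]
    return pattern[-1] + pattern[:-1]


def rotations(pattern: str, direction: Literal["left", "right"] = "left") -> list[str]:
    """The ``n - 1`` nontrivial cyclic rotations of ``pattern`` in shift order.

    >>> rotations("ATCG", "left")
    ['TCGA', 'CGAT', 'GATC']
    >>> rotations("ATCG", "right")
    ['GATC', 'CGAT', 'TCGA']
    """
    _check_pattern(pattern)
    out = []
    current = pattern
    for _ in range(len(pattern) - 1):
        current = rotate(current, direction)
        out.append(current)
    return out


def _validate(ref: ReferenceSequence, placement: Placement) -> None:
    pos, pat = placement.position, placement.pattern
    if placement.kind == "insertion":
        if not (ref.offset <= pos <= ref.end + 1):
            raise BoundsError(
                f"insertion position {pos} outside [{ref.offset}, {ref.end + 1}]"
            )
    else:
        last = pos + len(pat) - 1
        if not (ref.contains(pos) and ref.contains(last)):
            raise BoundsError(
                f"deletion [{pos}, {last}] outside [{ref.offset}, {ref.end}]"
            )
        observed = ref.slice(pos, last)
        if observed != pat:
            raise ReferenceMismatchError(
                f"deletion pattern {pat!r} != reference {observed!r} at {ref.contig}:{pos}"
            )


def apply_indel(ref: ReferenceSequence, placement: Placement) -> str:
    """Alternate sequence produced by applying one indel to the reference.

    For an insertion the pattern is spliced in so that its first base
    occupies ``placement.position`` in the alternate; for a deletion
    ``len(pattern)`` bases are removed starting at ``placement.position``.
    """
    _validate(ref, placement)
    i = placement.position - ref.offset
    if placement.kind == "insertion":
        return ref.bases[:i] + placement.pattern + ref.bases[i:]
    return ref.bases[:i] + ref.bases[i + len(placement.pattern) :]


def _candidate_positions(ref: ReferenceSequence, kind: IndelKind, length: int) -> range:
    if kind == "insertion":
        return range(ref.offset, ref.end + 2)
    return range(ref.offset, ref.end - length + 2)


def bruteforce_region(ref: ReferenceSequence, seed: Placement) -> frozenset[Placement]:
    """All placements equivalent to ``seed``, by direct enumeration.

    Tries every in-bounds position with every cyclic rotation of the seed
    pattern and keeps the placements whose alternate sequence equals the
    seed's.  The returned positions always form a contiguous interval
    (asserted): equivalent placements of one indel cannot skip positions.
    """
    target = apply_indel(ref, seed)
    pats = [seed.pattern] + rotations(seed.pattern)
    found: set[Placement] = set()
    for pos in _candidate_positions(ref, seed.kind, len(seed.pattern)):
        for pat in pats:
            cand = Placement(pos, pat, seed.kind)
            try:
                if apply_indel(ref, cand) == target:
                    found.add(cand)
                    break  # rotations may repeat (e.g. AAA); one hit per position
            except (ReferenceMismatchError, BoundsError):
                continue
    positions = sorted({p.position for p in found})
    assert positions == list(range(positions[0], positions[-1] + 1)), (
        "equivalence region is not contiguous — broken oracle or invariant"
    )
    return frozenset(found)


_EXHAUSTIVE_MAX_PATTERN = 3
_EXHAUSTIVE_MAX_REF = 15


def exhaustive_equivalents(ref: ReferenceSequence, seed: Placement) -> frozenset[Placement]:
    """Strong oracle: enumerate *all* same-length patterns at all positions.

    Unlike :func:`bruteforce_region`, candidate patterns are not restricted
    to rotations of the seed; the result confirming that only rotations
    ever appear is the empirical counterpart of the cyclic-permutation
    characterization of equivalent indels.  Guarded to tiny inputs
    (pattern length <= 3, reference
    length <= 15) because the search is exponential in pattern length.
    """
    if len(seed.pattern) > _EXHAUSTIVE_MAX_PATTERN or len(ref) > _EXHAUSTIVE_MAX_REF:
        raise ScaleLimitError(
            f"exhaustive search limited to patterns <= {_EXHAUSTIVE_MAX_PATTERN} "
            f"and references <= {_EXHAUSTIVE_MAX_REF} bases"
        )
    target = apply_indel(ref, seed)
    found: set[Placement] = set()
    for pos in _candidate_positions(ref, seed.kind, len(seed.pattern)):
        for chars in itertools.product("ACGT", repeat=len(seed.pattern)):
            cand = Placement(pos, "".join(chars), seed.kind)
            try:
                if apply_indel(ref, cand) == target:
                    found.add(cand)
            except (ReferenceMismatchError, BoundsError):
                continue
    return frozenset(found)


def region_placements(
    ref: ReferenceSequence, seed: Placement
) -> Iterator[Placement]:  # pragma: no cover - convenience alias
    """Iterate the brute-force equivalence region sorted by position."""
    yield from sorted(bruteforce_region(ref, seed))
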