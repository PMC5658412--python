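"""The universal-positioning (UPS) coordinate and the extension algorithm.

A UPS-coordinate ``±PATTERN[lower-upper]`` names an indel by its whole
region of equivalence instead of a single normalized position: the sign
gives the type (``+`` insertion, ``-`` deletion), the pattern is the
rotation valid at the leftmost placement, and ``[lower, upper]`` is the
inclusive range of first-affected-base positions at which equivalent
representations exist.  Two indel records denote the same mutation exactly
when their UPS-coordinates are equal as strings, which reduces redundancy
detection and call-set comparison to key equality.

The computation slides the seed placement outward one position at a time.
A shift is accepted precisely when the reference base crossing the event
boundary matches the rotation currently in force, in which case the
pattern rotates one step with it; the walk stops at the first mismatch or
at the contig edge.  Each accepted shift preserves the alternate sequence,
and by the cyclic-permutation characterization of equivalent indels no
placement outside the walked interval can be equivalent, so the interval
equals the brute-force region (tested exhaustively against
:func:`upsvcf.sequences.bruteforce_region`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol

from upsvcf.errors import UPSParseError
from upsvcf.sequences import Placement, ReferenceSequence, rotate, _validate


class _IndelLike(Protocol):
    position: int
    pattern: str
    kind: str


@dataclass(frozen=True, order=True)
class UPSCoordinate:
    """Sign, canonical pattern and inclusive equivalence range of an indel."""

    contig: str
    sign: str  # "+" insertion, "-" deletion
    pattern: str
    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.sign not in "+-":
            raise ValueError(f"sign must be '+' or '-', got {self.sign!r}")
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} > upper {self.upper}")

    @property
    def kind(self) -> str:
        return "insertion" if self.sign == "+" else "deletion"

    def __str__(self) -> str:
        return serialize_ups(self)


def _shift_insertion(ref: ReferenceSequence, pos: int, pattern: str, step: int) -> str | None:
    """Pattern after shifting an insertion placement by one, or None if illegal.

    Moving right from ``pos`` to ``pos + 1`` re-expresses the alternate with
    the boundary base ref[pos] absorbed on the left, which requires
    ref[pos] == pattern[0] and rotates the pattern left; moving left is the
    mirror image (ref[pos - 1] == pattern[-1], rotate right).
    """
    if step > 0:
        if ref.contains(pos) and ref.base(pos) == pattern[0]:
            return rotate(pattern, "left")
    else:
        if ref.contains(pos - 1) and ref.base(pos - 1) == pattern[-1]:
            return rotate(pattern, "right")
    return None


def _shift_deletion(ref: ReferenceSequence, pos: int, pattern: str, step: int) -> str | None:
    length = len(pattern)
    if step > 0:
        nxt = pos + length
        if ref.contains(nxt) and ref.base(pos) == ref.base(nxt):
            return rotate(pattern, "left")
    else:
        prev = pos - 1
        if ref.contains(prev) and ref.base(prev) == pattern[-1]:
            return rotate(pattern, "right")
    return None


def compute_ups(indel: _IndelLike, ref: ReferenceSequence) -> UPSCoordinate:
    """UPS-coordinate of one primitive indel against its reference.

    The seed placement must be valid on ``ref`` (for deletions the pattern
    must equal the reference substring it removes).  Extension is clamped
    at contig edges: running out of sequence stops the walk, it never
    raises.
    """
    seed = Placement(indel.position, indel.pattern, indel.kind)  # validates pattern
    _validate(ref, seed)
    shifter = _shift_insertion if seed.kind == "insertion" else _shift_deletion

    pos, pat = seed.position, seed.pattern
    while (nxt := shifter(ref, pos, pat, +1)) is not None:
        pos, pat = pos + 1, nxt
    upper = pos

    pos, pat = seed.position, seed.pattern
    while (prv := shifter(ref, pos, pat, -1)) is not None:
        pos, pat = pos - 1, prv
    lower, canonical = pos, pat

    sign = "+" if seed.kind == "insertion" else "-"
    return UPSCoordinate(ref.contig, sign, canonical, lower, upper)


def serialize_ups(ups: UPSCoordinate) -> str:
    """Canonical text form ``±PATTERN[lower-upper]`` (ASCII hyphen, no spaces)."""
    return f"{ups.sign}{ups.pattern}[{ups.lower}-{ups.upper}]"


# Lenient on typographic variants seen in print: optional spaces; the
# separator and a deletion sign may be a hyphen, en/em dash or minus sign.
_SIGN = {"+": "+", "-": "-", "−": "-", "–": "-", "—": "-"}
_UPS_RE = re.compile(
    r"\s*(?P<sign>[+\-−–—])\s*"
    r"(?P<pattern>[ACGTacgt]+)\s*"
    r"\[\s*(?P<lower>\d+)\s*[-−–—]\s*(?P<upper>\d+)\s*\]\s*$"
)


def parse_ups(text: str, contig: str = "") -> UPSCoordinate:
    """Parse a UPS-coordinate string, tolerating printed typography.

    Accepts e.g. ``"+TG[10009639-10009648]"`` and the spaced/en-dash form
    ``"+ TG[10009639 – 10009648]"``.  The contig is not part of the string
    grammar; pass it when the surrounding record provides one.
    """
    m = _UPS_RE.match(text)
    if m is None:
        # locate the first offending column for the error message
        probe = re.match(r"\s*[+\-−–—]", text)
        col = probe.end() if probe else 0
        raise UPSParseError(text, col, "expected SIGN PATTERN '[' INT - INT ']'")
    lower, upper = int(m["lower"]), int(m["upper"])
    if lower > upper:
        raise UPSParseError(text, m.start("lower"), f"lower {lower} > upper {upper}")
    return UPSCoordinate(contig, _SIGN[m["sign"]], m["pattern"].upper(), lower, upper)
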