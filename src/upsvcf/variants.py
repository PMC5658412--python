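"""From raw VCF alleles to primitive indel and SNV events.

A VCF record may carry several ALT alleles (split *vertically*, one event
per allele), redundant anchor bases shared between REF and ALT (trimmed
away), or a complex variant clumping a substitution with an indel (split
*horizontally* via global alignment).  This module performs all three
reductions, producing :class:`PrimitiveIndel` and :class:`PrimitiveSnv`
events in the coordinate conventions of :mod:`upsvcf.sequences`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from upsvcf.errors import InvalidAlleleError, UnresolvableAllele

_ACGT = frozenset("ACGT")
_ACGTN = frozenset("ACGTN")


@dataclass(frozen=True)
class VcfVariantRecord:
    """One VCF data line, mandatory columns parsed, the rest passed through."""

    contig: str
    pos: int
    id: str
    ref_allele: str
    alt_alleles: tuple[str, ...]
    passthrough: tuple[str, ...] = ()  # QUAL, FILTER, INFO, FORMAT, samples — verbatim

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele:
            raise ValueError("ref_allele must be nonempty")
        if any(not a for a in self.alt_alleles):
            raise ValueError("alt alleles must be nonempty")


@dataclass(frozen=True)
class PrimitiveIndel:
    """A single insertion or deletion event."""

    contig: str
    position: int  # first inserted / first deleted base
    kind: str  # "insertion" | "deletion"
    pattern: str
    source_id: str = "."
    source_alt_index: int = 0


@dataclass(frozen=True)
class PrimitiveSnv:
    """A single-base substitution (kept for reconstruction; never UPS-annotated)."""

    contig: str
    position: int
    ref_base: str
    alt_base: str
    source_id: str = "."


@dataclass(frozen=True)
class ComplexAllele:
    """Marker for a trimmed allele pair that is neither SNV nor pure indel."""

    position: int
    ref: str
    alt: str


class NoOp:
    """Marker for identical REF/ALT alleles (nothing to annotate)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "NoOp()"


NOOP = NoOp()

Classified = Union[PrimitiveIndel, PrimitiveSnv, ComplexAllele, NoOp]


def split_multiallelic(record: VcfVariantRecord) -> list[VcfVariantRecord]:
    """One record per ALT allele; every other field copied, order preserved."""
    if len(record.alt_alleles) <= 1:
        return [record]
    return [replace(record, alt_alleles=(alt,)) for alt in record.alt_alleles]


def _check_allele(allele: str) -> str:
    up = allele.upper()
    if not _ACGTN.issuperset(up):
        raise InvalidAlleleError(f"allele {allele!r} contains non-ACGTN characters")
    return up


def trim_and_classify(
    pos: int, ref_allele: str, alt_allele: str, *, contig: str = "", source_id: str = "."
) -> Classified:
    """Strip shared context and classify what remains.

    The longest shared prefix is removed first (advancing ``pos``), then
    the longest shared suffix.  An empty trimmed REF is a pure insertion,
    an empty trimmed ALT a pure deletion, one base against one base an
    SNV; anything longer on both sides is a complex variant to be routed
    to :func:`nw_decompose`.  Identical alleles classify as no-op.

    Raises :class:`UnresolvableAllele` if an N survives inside the trimmed
    event (such records pass through unannotated downstream).
    """
    ref = _check_allele(ref_allele)
    alt = _check_allele(alt_allele)
    if ref == alt:
        return NOOP

    # prefix first, then suffix (either order yields the same UPS region
    # after canonicalization; this order is fixed for determinism)
    n_pre = 0
    while n_pre < min(len(ref), len(alt)) and ref[n_pre] == alt[n_pre]:
        n_pre += 1
    pos += n_pre
    ref, alt = ref[n_pre:], alt[n_pre:]
    n_suf = 0
    while n_suf < min(len(ref), len(alt)) and ref[-1 - n_suf] == alt[-1 - n_suf]:
        n_suf += 1
    if n_suf:
        ref, alt = ref[: len(ref) - n_suf], alt[: len(alt) - n_suf]

    if "N" in ref or "N" in alt:
        raise UnresolvableAllele(f"N inside event region at {contig or '?'}:{pos}")
    if not ref:
        return PrimitiveIndel(contig, pos, "insertion", alt, source_id)
    if not alt:
        return PrimitiveIndel(contig, pos, "deletion", ref, source_id)
    if len(ref) == 1 and len(alt) == 1:
        return PrimitiveSnv(contig, pos, ref, alt, source_id)
    return ComplexAllele(pos, ref, alt)


# -- global alignment for horizontal decomposition ---------------------------

DEFAULT_SCORES = (2, -1, -2)  # match, mismatch, gap (linear)


def _nw_align(ref: str, alt: str, scores: tuple[int, int, int]) -> list[tuple[str, str]]:
    """Optimal global alignment as a list of (ref_char|'-', alt_char|'-') columns.

    Ties are broken so that substitutions land as far left as possible with
    gap runs after them, which is what the deterministic decomposition
    contract requires.  Implemented by aligning the reversed strings with a
    diagonal > up > left end-to-start traceback and reversing the result.
    """
    match, mismatch, gap = scores
    r, a = ref[::-1], alt[::-1]
    m, n = len(r), len(a)
    dp = np.empty((m + 1, n + 1), dtype=np.int64)
    dp[:, 0] = gap * np.arange(m + 1)
    dp[0, :] = gap * np.arange(n + 1)
    for i in range(1, m + 1):
        ri = r[i - 1]
        for j in range(1, n + 1):
            s = match if ri == a[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + s, dp[i - 1, j] + gap, dp[i, j - 1] + gap)
    cols: list[tuple[str, str]] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if r[i - 1] == a[j - 1] else mismatch
            if dp[i, j] == dp[i - 1, j - 1] + s:
                cols.append((r[i - 1], a[j - 1]))
                i, j = i - 1, j - 1
                continue
        if i > 0 and dp[i, j] == dp[i - 1, j] + gap:
            cols.append((r[i - 1], "-"))
            i -= 1
            continue
        cols.append(("-", a[j - 1]))
        j -= 1
    # cols were collected end-to-start over reversed strings: already in
    # original left-to-right order.
    return cols


def nw_alignment_score(ref: str, alt: str, scores: tuple[int, int, int] = DEFAULT_SCORES) -> int:
    """Score of the optimal global alignment (for cross-checking)."""
    match, mismatch, gap = scores
    return sum(
        gap if "-" in col else (match if col[0] == col[1] else mismatch)
        for col in _nw_align(ref, alt, scores)
    )


def nw_decompose(
    pos: int,
    ref_allele: str,
    alt_allele: str,
    scores: tuple[int, int, int] = DEFAULT_SCORES,
    *,
    contig: str = "",
    source_id: str = ".",
) -> list[Union[PrimitiveIndel, PrimitiveSnv]]:
    """Decompose a complex variant into primitive SNVs and indels.

    The REF and ALT alleles are globally aligned under ``scores``
    (match, mismatch, linear gap); mismatch columns become SNVs and
    maximal runs of gap columns become one insertion or deletion each.
    Applying the returned primitives left to right to ``ref_allele``
    reconstructs ``alt_allele`` exactly.

    >>> nw_decompose(100, "ATAA", "AG")  # doctest: +NORMALIZE_WHITESPACE
    [PrimitiveSnv(contig='', position=101, ref_base='T', alt_base='G', source_id='.'),
     PrimitiveIndel(contig='', position=102, kind='deletion', pattern='AA',
                    source_id='.', source_alt_index=0)]
    """
    ref = _check_allele(ref_allele)
    alt = _check_allele(alt_allele)
    if "N" in ref or "N" in alt:
        raise UnresolvableAllele(f"N in complex allele at {contig or '?'}:{pos}")
    cols = _nw_align(ref, alt, scores)
    out: list[Union[PrimitiveIndel, PrimitiveSnv]] = []
    ref_pos = pos  # position of the next reference base to be consumed
    i = 0
    while i < len(cols):
        rc, ac = cols[i]
        if rc != "-" and ac != "-":
            if rc != ac:
                out.append(PrimitiveSnv(contig, ref_pos, rc, ac, source_id))
            ref_pos += 1
            i += 1
        elif ac == "-":  # run of deleted reference bases
            run = []
            start = ref_pos
            while i < len(cols) and cols[i][1] == "-":
                run.append(cols[i][0])
                ref_pos += 1
                i += 1
            out.append(PrimitiveIndel(contig, start, "deletion", "".join(run), source_id))
        else:  # run of inserted alt bases, placed before the next ref base
            run = []
            while i < len(cols) and cols[i][0] == "-":
                run.append(cols[i][1])
                i += 1
            out.append(PrimitiveIndel(contig, ref_pos, "insertion", "".join(run), source_id))
    return out


def reconstruct(ref_allele: str, primitives: list[Union[PrimitiveIndel, PrimitiveSnv]], pos: int) -> str:
    """Apply decomposition primitives to ``ref_allele``; inverse of decompose.

    ``pos`` is the genomic position of the first base of ``ref_allele``.
    Used by tests to verify the reconstruction invariant.
    """
    # Right-to-left so earlier edits don't shift later coordinates; at a
    # shared position an insertion precedes the base in sequence order, so
    # it must be applied after the substitution/deletion at that base.
    def order(p):
        is_ins = isinstance(p, PrimitiveIndel) and p.kind == "insertion"
        return (p.position, 0 if is_ins else 1)

    seq = list(ref_allele)
    for p in sorted(primitives, key=order, reverse=True):
        i = p.position - pos
        if isinstance(p, PrimitiveSnv):
            assert seq[i] == p.ref_base
            seq[i] = p.alt_base
        elif p.kind == "deletion":
            assert "".join(seq[i : i + len(p.pattern)]) == p.pattern
            del seq[i : i + len(p.pattern)]
        else:
            seq[i:i] = list(p.pattern)
    return "".join(seq)
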