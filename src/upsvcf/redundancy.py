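"""Redundancy detection, filtering and call-set comparison over UPS keys.

Once every indel carries its UPS-coordinate, two records denote the same
mutation exactly when their full keys — contig, sign, canonical pattern
and equivalence range — are equal.  The range alone is not sufficient: an
insertion and a deletion can share a range in the same repeat tract yet
alter the sequence differently, so the sign and pattern stay part of the
key.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from upsvcf.errors import UndefinedRatioError
from upsvcf.ups import UPSCoordinate, serialize_ups
from upsvcf.uvcf import UVCFRecord


class UPSKey(NamedTuple):
    """Hashable identity of an annotated indel, with a deterministic order."""

    contig: str
    lower: int
    upper: int
    sign: str
    pattern: str

    @classmethod
    def of(cls, ups: UPSCoordinate) -> "UPSKey":
        return cls(ups.contig, ups.lower, ups.upper, ups.sign, ups.pattern)

    def __str__(self) -> str:
        text = serialize_ups(
            UPSCoordinate(self.contig, self.sign, self.pattern, self.lower, self.upper)
        )
        return f"{self.contig}:{text}" if self.contig else text


@dataclass(frozen=True)
class RedundantGroup:
    """Records sharing one UPS key; only groups of two or more are reported."""

    key: UPSKey
    members: tuple[tuple[str, int], ...]  # (record id, original POS), ordered

    def __len__(self) -> int:
        return len(self.members)

    def to_line(self) -> str:
        ids = ",".join(mid for mid, _ in self.members)
        return f"{self.key}\t{ids}"


def group_redundant(records: Iterable[UVCFRecord]) -> list[RedundantGroup]:
    """Group annotated rows by exact UPS-key equality.

    Rows without an annotation are ignored.  Groups are sorted by key and
    members by (position, id), so output is deterministic.
    """
    buckets: dict[UPSKey, list[tuple[str, int]]] = {}
    for rec in records:
        if rec.ups is None:
            continue
        buckets.setdefault(UPSKey.of(rec.ups), []).append((rec.id, rec.pos))
    return [
        RedundantGroup(key, tuple(sorted(members, key=lambda m: (m[1], m[0]))))
        for key, members in sorted(buckets.items())
        if len(members) >= 2
    ]


def redundant_ratio(n_total: int, groups: Sequence[RedundantGroup]) -> float:
    """Fraction of records that are redundant copies of another record.

    Each group of size *k* contributes *k - 1* redundant records (one
    representative per group is kept), so the ratio is
    ``(sum of group sizes - number of groups) / n_total``.
    """
    if n_total <= 0:
        raise UndefinedRatioError("redundant ratio undefined for an empty call set")
    n_members = sum(len(g) for g in groups)
    if n_members > n_total:
        raise ValueError(f"groups contain {n_members} members but n_total={n_total}")
    return (n_members - len(groups)) / n_total


def filter_redundant(
    records: Iterable[UVCFRecord], groups: Sequence[RedundantGroup] | None = None
) -> list[UVCFRecord]:
    """Keep one representative per redundant group; drop the other copies.

    The representative is the member with the smallest (POS, id); rows not
    in any group pass through; input order is preserved.  When ``groups``
    is omitted they are computed from the records themselves.
    """
    records = list(records)
    if groups is None:
        groups = group_redundant(records)
    representative = {g.key: g.members[0] for g in groups}
    grouped_keys = set(representative)
    out: list[UVCFRecord] = []
    seen_rep: set[UPSKey] = set()
    for rec in records:
        if rec.ups is None:
            out.append(rec)
            continue
        key = UPSKey.of(rec.ups)
        if key not in grouped_keys:
            out.append(rec)
        elif (rec.id, rec.pos) == representative[key] and key not in seen_rep:
            # the (pos, id)-minimal member; duplicates of it are still dropped
            out.append(rec)
            seen_rep.add(key)
    return out


@dataclass(frozen=True)
class ComparisonReport:
    """Key-overlap statistics between two annotated call sets."""

    name_a: str
    name_b: str
    total_a: int  # annotated indel rows
    total_b: int
    insertions_a: int
    deletions_a: int
    insertions_b: int
    deletions_b: int
    distinct_a: int  # distinct UPS keys
    distinct_b: int
    common: int
    unique_a: int
    unique_b: int
    jaccard: float

    def to_text(self) -> str:
        lines = [
            f"set_a\t{self.name_a}",
            f"set_b\t{self.name_b}",
            f"records_a\t{self.total_a}",
            f"records_b\t{self.total_b}",
            f"insertions_a\t{self.insertions_a}",
            f"deletions_a\t{self.deletions_a}",
            f"insertions_b\t{self.insertions_b}",
            f"deletions_b\t{self.deletions_b}",
            f"distinct_keys_a\t{self.distinct_a}",
            f"distinct_keys_b\t{self.distinct_b}",
            f"common\t{self.common}",
            f"unique_a\t{self.unique_a}",
            f"unique_b\t{self.unique_b}",
            f"jaccard\t{self.jaccard:.4f}",
        ]
        return "\n".join(lines)


def _summarize(records: Iterable[UVCFRecord]):
    total = ins = dels = 0
    keys: set[UPSKey] = set()
    contigs: set[str] = set()
    for rec in records:
        if rec.ups is None:
            continue
        total += 1
        if rec.ups.sign == "+":
            ins += 1
        else:
            dels += 1
        keys.add(UPSKey.of(rec.ups))
        contigs.add(rec.contig)
    return total, ins, dels, keys, contigs


def compare_sets(
    a: Iterable[UVCFRecord],
    b: Iterable[UVCFRecord],
    *,
    name_a: str = "A",
    name_b: str = "B",
    strict_contigs: bool = False,
) -> ComparisonReport:
    """Compare two annotated call sets by distinct-UPS-key intersection.

    A key present several times in one set (duplicate rows) counts once.
    Both sets must be annotated against the same reference build; disjoint
    contig name sets trigger a warning (or a failure with
    ``strict_contigs=True``).
    """
    ta, ia, da, ka, ca = _summarize(a)
    tb, ib, db, kb, cb = _summarize(b)
    if ca and cb and not (ca & cb):
        msg = f"call sets share no contig names: {sorted(ca)[:3]} vs {sorted(cb)[:3]}"
        if strict_contigs:
            raise ValueError(msg)
        import logging

        logging.getLogger("upsvcf").warning(msg)
    common = len(ka & kb)
    union = len(ka | kb)
    return ComparisonReport(
        name_a,
        name_b,
        ta,
        tb,
        ia,
        da,
        ib,
        db,
        len(ka),
        len(kb),
        common,
        len(ka) - common,
        len(kb) - common,
        common / union if union else 0.0,
    )


def distance_match(
    a: Iterable,
    b: Iterable,
    window: int = 5,
    same_pattern: bool = True,
) -> int:
    """Count matches under the classical position-window baseline.

    Two indels match when they are of the same type, carry the same
    literal pattern (unless ``same_pattern=False``), and sit within
    ``window`` base pairs of each other on the same contig.  Matching is
    one-to-one and greedy: both sides are sorted by position and each
    record takes the earliest still-unmatched partner.  This is the
    baseline the UPS comparison is measured against — it misses
    equivalent pairs whose separation exceeds the window or whose stored
    patterns are different rotations.

    Accepts any records with ``contig``, ``position``, ``kind`` and
    ``pattern`` attributes (e.g. :class:`upsvcf.variants.PrimitiveIndel`).
    """

    def keyed(items):
        out: dict[tuple, list[int]] = {}
        for it in sorted(items, key=lambda x: (x.contig, x.position)):
            k = (it.contig, it.kind, it.pattern if same_pattern else len(it.pattern))
            out.setdefault(k, []).append(it.position)
        return out

    left, right = keyed(a), keyed(b)
    matches = 0
    for k, positions_a in left.items():
        positions_b = right.get(k)
        if not positions_b:
            continue
        used = [False] * len(positions_b)
        j = 0
        for pa in positions_a:
            while j < len(positions_b) and positions_b[j] < pa - window:
                j += 1
            for jj in range(j, len(positions_b)):
                if positions_b[jj] > pa + window:
                    break
                if not used[jj]:
                    used[jj] = True
                    matches += 1
                    break
    return matches
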