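"""Reading VCF and FASTA, writing UVCF, and the annotation pipeline.

UVCF is ordinary VCF with one extra column appended: the last column,
named ``UPS-COORDINATE`` on the ``#CHROM`` header line, carries the
serialized UPS-coordinate for rows holding a primitive indel and ``"."``
for everything else (SNVs, monomorphic rows, records that could not be
annotated).  Because the extra column makes the file non-standard VCF,
reading and writing here is deliberately line-based: the mandatory
columns are parsed, every trailing column is carried verbatim, and the
header is preserved byte for byte.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Union

import pyfaidx

from upsvcf.errors import (
    BoundsError,
    InvalidAlleleError,
    MissingContigError,
    ReferenceMismatchError,
    UnresolvableAllele,
    UPSParseError,
    VcfFormatError,
)
from upsvcf.sequences import ReferenceSequence
from upsvcf.ups import UPSCoordinate, compute_ups, parse_ups, serialize_ups
from upsvcf.variants import (
    ComplexAllele,
    NoOp,
    PrimitiveIndel,
    PrimitiveSnv,
    VcfVariantRecord,
    nw_decompose,
    split_multiallelic,
    trim_and_classify,
)

logger = logging.getLogger("upsvcf")

UPS_COLUMN = "UPS-COORDINATE"

_ACGTN = frozenset("ACGTN")


@dataclass(frozen=True)
class UVCFRecord:
    """One UVCF row: a (post-split) VCF record plus its UPS annotation."""

    contig: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str  # single allele after vertical splitting; "." if none
    passthrough: tuple[str, ...] = ()
    ups: UPSCoordinate | None = None

    def to_line(self) -> str:
        cols = [
            self.contig,
            str(self.pos),
            self.id,
            self.ref_allele,
            self.alt_allele,
            *self.passthrough,
            serialize_ups(self.ups) if self.ups is not None else ".",
        ]
        return "\t".join(cols)


# -- primitive readers -------------------------------------------------------


def _open_text(path: Union[str, Path]):
    """Open plain or gzip-compressed text transparently."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def load_reference(path: Union[str, Path], contig: str | None = None) -> ReferenceSequence:
    """Load one contig from a (possibly multi-contig, faidx-indexed) FASTA.

    With ``contig=None`` the FASTA must contain exactly one sequence.
    Bases are uppercased; the returned offset is 1.
    """
    fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    names = list(fasta.keys())
    if contig is None:
        if len(names) != 1:
            raise MissingContigError(
                f"FASTA has {len(names)} contigs; specify one of {names[:5]}"
            )
        contig = names[0]
    if contig not in fasta:
        raise MissingContigError(f"contig {contig!r} not in {path}")
    return ReferenceSequence(contig, 1, str(fasta[contig][:]))


def read_vcf_header(path: Union[str, Path]) -> list[str]:
    """All header lines (``##...`` and the ``#CHROM`` line) verbatim."""
    header = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header.append(line.rstrip("\n"))
    return header


def _parse_data_line(line: str, lineno: int) -> VcfVariantRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise VcfFormatError(lineno, f"expected >= 5 tab-separated columns, got {len(fields)}")
    contig, pos_s, vid, ref, alt = fields[:5]
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfFormatError(lineno, f"POS {pos_s!r} is not an integer") from None
    if pos < 1 or not ref:
        raise VcfFormatError(lineno, "POS must be >= 1 and REF nonempty")
    alts = () if alt == "." else tuple(alt.split(","))
    if any(not a for a in alts):
        raise VcfFormatError(lineno, f"empty ALT allele in {alt!r}")
    return VcfVariantRecord(contig, pos, vid, ref, alts, tuple(fields[5:]))


def read_vcf(path: Union[str, Path], on_error: str = "raise") -> Iterator[VcfVariantRecord]:
    """Stream data lines of a VCF 4.x file (plain or gzipped) in file order.

    ``on_error="skip"`` logs malformed data lines with their line number
    and continues; the default raises :class:`VcfFormatError`.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            try:
                yield _parse_data_line(line, lineno)
            except VcfFormatError as exc:
                if on_error == "skip":
                    logger.warning("skipping malformed record: %s", exc)
                    continue
                raise


# -- annotation pipeline -----------------------------------------------------

RefProvider = Callable[[str], ReferenceSequence]


def _as_provider(ref: Union[ReferenceSequence, RefProvider, str, Path]) -> RefProvider:
    if isinstance(ref, ReferenceSequence):
        def single(contig: str) -> ReferenceSequence:
            if contig != ref.contig:
                raise MissingContigError(f"contig {contig!r} != loaded {ref.contig!r}")
            return ref

        return single
    if isinstance(ref, (str, Path)):
        fasta = pyfaidx.Fasta(str(ref), as_raw=True, sequence_always_upper=True)
        cache: dict[str, ReferenceSequence] = {}

        def from_fasta(contig: str) -> ReferenceSequence:
            if contig not in cache:
                if contig not in fasta:
                    raise MissingContigError(f"contig {contig!r} not in FASTA")
                cache[contig] = ReferenceSequence(contig, 1, str(fasta[contig][:]))
            return cache[contig]

        return from_fasta
    return ref


def _handle_invalid(mode: str, message: str) -> bool:
    """Return True when an unannotated row should still be emitted."""
    if mode == "fail":
        raise ReferenceMismatchError(message)
    if mode == "skip":
        logger.warning("skipping record: %s", message)
        return False
    logger.warning("%s (row emitted without annotation)", message)
    return True


def annotate_records(
    records: Iterable[VcfVariantRecord],
    reference: Union[ReferenceSequence, RefProvider, str, Path],
    *,
    hd: bool = True,
    emit_snv_rows: bool = True,
    validate: str = "warn",
    scores: tuple[int, int, int] | None = None,
) -> Iterator[UVCFRecord]:
    """Run the full pipeline over parsed VCF records.

    Per record: vertical (multiallelic) split, then allele trimming and
    classification; complex variants are horizontally decomposed by global
    alignment when ``hd`` is true; each resulting primitive indel is
    annotated with its UPS-coordinate against the original reference.
    SNVs, monomorphic rows and records that cannot be resolved are emitted
    with an absent annotation.  ``validate`` controls REF-allele /
    reference disagreements and out-of-bounds placements: ``"warn"``
    (default) emits the row unannotated, ``"skip"`` drops it, ``"fail"``
    raises.
    """
    provider = _as_provider(reference)
    from upsvcf.variants import DEFAULT_SCORES

    scores = scores or DEFAULT_SCORES
    for record in records:
        for sub in split_multiallelic(record):
            row = lambda ups=None: UVCFRecord(  # noqa: E731
                sub.contig,
                sub.pos,
                sub.id,
                sub.ref_allele,
                sub.alt_alleles[0] if sub.alt_alleles else ".",
                sub.passthrough,
                ups,
            )
            if not sub.alt_alleles:
                yield row()
                continue
            alt = sub.alt_alleles[0]
            if not _ACGTN.issuperset(alt.upper()) or not _ACGTN.issuperset(
                sub.ref_allele.upper()
            ):
                # symbolic ALT (<DEL>, breakend, *) or nonstandard REF
                yield row()
                continue
            try:
                ref = provider(sub.contig)
            except MissingContigError as exc:
                if _handle_invalid(validate, str(exc)):
                    yield row()
                continue
            # REF allele must agree with the reference sequence
            try:
                observed = ref.slice(sub.pos, sub.pos + len(sub.ref_allele) - 1)
            except BoundsError:
                observed = None
            if observed != sub.ref_allele.upper():
                msg = (
                    f"REF {sub.ref_allele!r} disagrees with reference at "
                    f"{sub.contig}:{sub.pos}"
                )
                if _handle_invalid(validate, msg):
                    yield row()
                continue
            try:
                event = trim_and_classify(
                    sub.pos, sub.ref_allele, alt, contig=sub.contig, source_id=sub.id
                )
            except (UnresolvableAllele, InvalidAlleleError) as exc:
                logger.warning("%s (row emitted without annotation)", exc)
                yield row()
                continue

            if isinstance(event, (NoOp, PrimitiveSnv)):
                yield row()
            elif isinstance(event, PrimitiveIndel):
                yield from _annotated_rows(row, [event], ref, validate, emit_snv_rows)
            else:  # ComplexAllele
                if not hd:
                    yield row()
                    continue
                prims = nw_decompose(
                    event.position,
                    event.ref,
                    event.alt,
                    scores,
                    contig=sub.contig,
                    source_id=sub.id,
                )
                yield from _annotated_rows(row, prims, ref, validate, emit_snv_rows)


def _annotated_rows(row, primitives, ref, validate, emit_snv_rows):
    for prim in primitives:
        if isinstance(prim, PrimitiveSnv):
            if emit_snv_rows:
                yield row()
            continue
        try:
            ups = compute_ups(prim, ref)
        except (BoundsError, ReferenceMismatchError) as exc:
            if _handle_invalid(validate, str(exc)):
                yield row()
            continue
        yield row(ups)


def _uvcf_header(vcf_header: list[str]) -> list[str]:
    header = list(vcf_header)
    for i, line in enumerate(header):
        if line.startswith("#CHROM") or (line.startswith("#") and not line.startswith("##")):
            header[i] = line + "\t" + UPS_COLUMN
            return header
    header.append("#CHROM\tPOS\tID\tREF\tALT\t" + UPS_COLUMN)
    return header


def write_uvcf(
    path: Union[str, Path],
    records: Iterable[UVCFRecord],
    header: list[str] | None = None,
) -> int:
    """Write UVCF rows (returns the number of data rows written)."""
    n = 0
    with open(path, "w", encoding="utf-8") as out:
        for line in _uvcf_header(header or []):
            out.write(line + "\n")
        for rec in records:
            out.write(rec.to_line() + "\n")
            n += 1
    return n


def annotate(
    vcf_path: Union[str, Path],
    fasta_path: Union[str, Path],
    out_path: Union[str, Path] | None = None,
    *,
    hd: bool = True,
    emit_snv_rows: bool = True,
    validate: str = "warn",
    on_error: str = "raise",
) -> Union[int, Iterator[UVCFRecord]]:
    """Annotate a VCF file against a FASTA reference.

    With ``out_path`` given, writes the UVCF file (input header preserved,
    ``UPS-COORDINATE`` appended to the column header line) and returns the
    row count; with ``out_path=None``, returns the record stream instead.
    """
    stream = annotate_records(
        read_vcf(vcf_path, on_error=on_error),
        fasta_path,
        hd=hd,
        emit_snv_rows=emit_snv_rows,
        validate=validate,
    )
    if out_path is None:
        return stream
    return write_uvcf(out_path, stream, read_vcf_header(vcf_path))


def read_uvcf(path: Union[str, Path]) -> Iterator[UVCFRecord]:
    """Stream rows of a UVCF file; the last column is the UPS annotation."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise VcfFormatError(lineno, f"expected >= 6 columns, got {len(fields)}")
            rec = _parse_data_line("\t".join(fields[:-1]), lineno)
            ups_text = fields[-1]
            if ups_text == ".":
                ups = None
            else:
                try:
                    ups = parse_ups(ups_text, contig=rec.contig)
                except UPSParseError as exc:
                    raise VcfFormatError(lineno, str(exc)) from exc
            yield UVCFRecord(
                rec.contig,
                rec.pos,
                rec.id,
                rec.ref_allele,
                rec.alt_alleles[0] if rec.alt_alleles else ".",
                rec.passthrough,
                ups,
            )
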