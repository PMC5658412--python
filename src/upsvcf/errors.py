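"""Exception hierarchy shared across the package."""


class UpsvcfError(Exception):
    """Base class for all package errors."""


class InvalidPatternError(UpsvcfError, ValueError):
    """A pattern string is empty or contains non-ACGT characters."""


class BoundsError(UpsvcfError, ValueError):
    """A genomic position falls outside the stored reference interval."""


class ReferenceMismatchError(UpsvcfError, ValueError):
    """A deletion pattern disagrees with the reference bases it claims to remove."""


class ScaleLimitError(UpsvcfError, ValueError):
    """An exhaustive enumeration was requested beyond its combinatorial guard."""


class InvalidAlleleError(UpsvcfError, ValueError):
    """A VCF allele contains characters outside A, C, G, T, N."""


class UnresolvableAllele(UpsvcfError):
    """An allele event region contains N; the record cannot be annotated."""


class UPSParseError(UpsvcfError, ValueError):
    """A UPS-coordinate string does not match the grammar."""

    def __init__(self, text: str, column: int, reason: str):
        self.text = text
        self.column = column
        self.reason = reason
        super().__init__(f"cannot parse UPS-coordinate {text!r} at column {column}: {reason}")


class VcfFormatError(UpsvcfError, ValueError):
    """A VCF/UVCF data line violates the mandatory-column contract."""

    def __init__(self, line_number: int, reason: str):
        self.line_number = line_number
        self.reason = reason
        super().__init__(f"line {line_number}: {reason}")


class MissingContigError(UpsvcfError, KeyError):
    """A requested contig is absent from the FASTA."""


class UndefinedRatioError(UpsvcfError, ZeroDivisionError):
    """The redundant-indel ratio is undefined for an empty call set."""


class FixtureSizingError(UpsvcfError, ValueError):
    """A fixture specification cannot fit in the requested contig length."""
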