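"""FASTA input, validation and strand operations.

All sequences are normalized to uppercase DNA over the alphabet {A, C, G, T, N}
(RNA input is accepted and U is mapped to T).  Coordinates throughout the
package are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Optional

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Characters accepted in raw input records (case-insensitive).
INPUT_ALPHABET = frozenset("ATCGUN")
#: Characters of a normalized sequence.
DNA_ALPHABET = frozenset("ACGTN")

#: Pasted-input size of the original web service; exceeding it is fine for the
#: stand-alone tool but worth a log line.
WEB_SIZE_CAP = 300_000


class FastaFormatError(ValueError):
    """Raised when the input text is not parseable FASTA."""


@dataclass(frozen=True)
class InputSequence:
    """A named, validated nucleotide sequence.

    Parameters
    ----------
    name : str
        Record identifier (header text up to the first whitespace).
    residues : str
        Normalized residues, uppercase DNA over ``{A,C,G,T,N}``.
    anchor : tuple, optional
        ``(chromosome, 1-based inclusive start, strand)`` genomic anchor used
        to remap local coordinates onto a chromosome.
    full_header : str, optional
        The complete FASTA header line (without ``>``), retained for
        provenance; outputs use ``name``.
    """

    name: str
    residues: str
    anchor: Optional[tuple[str, int, str]] = None
    full_header: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.name!r} is empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )
        if self.anchor is not None:
            chrom, start, strand = self.anchor
            if start < 1:
                raise ValueError("anchor start is 1-based and must be >= 1")
            if strand not in ("+", "-"):
                raise ValueError(f"anchor strand must be '+' or '-', got {strand!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ValidationReport:
    """PASS/FAIL status of one raw input record."""

    name: str
    status: str  # "PASS" or "FAIL"
    reason: str = ""

    @property
    def passed(self) -> bool:
        return self.status == "PASS"


def read_fasta(stream: IO[str] | Iterable[str]) -> list[tuple[str, str]]:
    """Split a FASTA text stream into ``(name, raw residues)`` pairs.

    Records are delimited by ``>`` header lines; the name is the header text
    up to the first whitespace; sequence lines are concatenated with
    surrounding whitespace removed.  No alphabet checking happens here (see
    :func:`validate_and_normalize`).

    Raises
    ------
    FastaFormatError
        If the stream is empty or sequence data precedes the first header;
        the message identifies the offending line number.
    """
    records: list[tuple[str, str]] = []
    name: Optional[str] = None
    chunks: list[str] = []
    saw_any = False
    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        saw_any = True
        if stripped.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = stripped[1:].split()[0] if stripped[1:].split() else ""
            chunks = []
        else:
            if name is None:
                raise FastaFormatError(
                    f"line {lineno}: sequence data before any '>' header"
                )
            chunks.append(stripped)
    if not saw_any:
        raise FastaFormatError("empty FASTA stream")
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def validate_and_normalize(
    name: str, raw: str
) -> tuple[ValidationReport, Optional[InputSequence]]:
    """Check one raw record against the input alphabet and normalize it.

    PASS requires a non-empty record whose characters (case-insensitive) all
    lie in ``{A,T,C,G,U,N}``.  On PASS the residues are uppercased and U is
    replaced by T.  Failures are reported, not raised, so multi-record input
    continues past a bad record.
    """
    if not raw:
        return ValidationReport(name, "FAIL", "empty sequence"), None
    upper = raw.upper()
    bad = set(upper) - INPUT_ALPHABET
    if bad:
        shown = ", ".join(repr(c) for c in sorted(bad))
        return (
            ValidationReport(name, "FAIL", f"invalid character(s): {shown}"),
            None,
        )
    if len(upper) > WEB_SIZE_CAP:
        logger.warning(
            "record %s is %d nt, above the %d-letter web-service cap "
            "(fine for the stand-alone tool)",
            name, len(upper), WEB_SIZE_CAP,
        )
    return (
        ValidationReport(name, "PASS"),
        InputSequence(name=name, residues=upper.replace("U", "T")),
    )


def reverse_complement(residues: str) -> str:
    """Reverse complement over ``{A,C,G,T,N}`` (N maps to N)."""
    bad = set(residues) - DNA_ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters: {sorted(bad)}")
    return str(Seq(residues).reverse_complement())


def write_fasta(records: Iterable[tuple[str, str]], sink: IO[str], width: int = 60) -> int:
    """Write ``(name, residues)`` pairs as FASTA wrapped at ``width`` columns."""
    n = 0
    for name, residues in records:
        sink.write(f">{name}\n")
        for i in range(0, len(residues), width):
            sink.write(residues[i : i + width] + "\n")
        n += 1
    return n
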