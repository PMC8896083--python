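"""Protein sequence input/output and coordinate conventions.

All residue coordinates in this package are 1-based and inclusive, matching
the numbering used in the calmodulin literature (a domain printed as
``1221LQALLLKRFLLARRSRRGLF1240`` spans residues 1221-1240 of the full-length
protein).

Two notations are supported:

* standard multi-record FASTA (via Biopython), and
* the "printed domain string" notation common in review articles, an
  optional leading start coordinate, the literal residue letters, and an
  optional trailing end coordinate.

Only the 20 standard amino-acid letters plus ``X`` (unknown) are accepted;
extended codes such as ``U`` or ``B`` are rejected at parse time because a
silently accepted non-standard letter could corrupt anchor counting
downstream.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted on input; X marks an unknown residue and never anchors
VALID_AA = STANDARD_AA | frozenset("X")

COORD_CONSISTENT = "consistent"
COORD_INCONSISTENT = "inconsistent"
COORD_ABSENT = "absent"


class SequenceValidationError(ValueError):
    """A sequence contains a character outside the accepted alphabet."""


class FastaError(ValueError):
    """FASTA input could not be interpreted (e.g. no records at all)."""


class DomainStringError(ValueError):
    """Printed domain-string notation could not be parsed."""


def _validate_sequence(sequence: str, *, owner: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise SequenceValidationError(f"{owner}: sequence is empty")
    for pos, letter in enumerate(seq, start=1):
        if letter not in VALID_AA:
            raise SequenceValidationError(
                f"{owner}: illegal residue {letter!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus a validated, upper-cased amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _validate_sequence(self.sequence, owner=self.id or "<record>")
        )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain sequence with optional coordinates in the parent protein.

    ``coordinate_flag`` is ``consistent`` exactly when both coordinates are
    present and ``end - start + 1`` equals the literal sequence length. The
    literal residue letters are always authoritative; coordinates that fail
    the arithmetic are kept but flagged ``inconsistent`` rather than
    silently corrected.
    """

    protein_id: str
    sequence: str
    start: int | None = None
    end: int | None = None
    coordinate_flag: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "sequence",
            _validate_sequence(self.sequence, owner=self.protein_id or "<domain>"),
        )
        if self.start is None or self.end is None:
            flag = COORD_ABSENT
        elif self.end - self.start + 1 == len(self.sequence):
            flag = COORD_CONSISTENT
        else:
            flag = COORD_INCONSISTENT
        object.__setattr__(self, "coordinate_flag", flag)

    @property
    def length(self) -> int:
        return len(self.sequence)


def parse_fasta(stream: Union[str, TextIO]) -> list[ProteinRecord]:
    """Read a multi-record FASTA stream into validated :class:`ProteinRecord`.

    Accepts either an open text handle or the FASTA text itself. Record
    order is preserved and sequences are upper-cased. An input with no
    records raises :class:`FastaError`; an illegal residue raises
    :class:`SequenceValidationError` naming the record and position.
    """
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(handle, "fasta")
    ]
    if not records:
        raise FastaError("no records found in FASTA input")
    return records


def write_fasta(records: Iterable[ProteinRecord], handle: TextIO | None = None) -> str:
    """Write records as FASTA; returns the text (also written to *handle*)."""
    out = io.StringIO()
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(seq_records, out, "fasta")
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text


_DOMAIN_RE = re.compile(r"\A(?P<start>\d+)?(?P<seq>[A-Za-z]+)(?P<end>\d+)?\Z")


def parse_domain_string(text: str, protein_id: str = "") -> DomainAnnotation:
    """Parse printed domain-string notation like ``1221LQALL...GLF1240``.

    The leading and trailing integers, when present, become the 1-based
    start and end coordinates; the residue letters in between are the
    domain sequence and are never altered by coordinate arithmetic.
    """
    match = _DOMAIN_RE.match(text.strip())
    if match is None or not match.group("seq"):
        raise DomainStringError(f"not a printed domain string: {text!r}")
    start = match.group("start")
    end = match.group("end")
    return DomainAnnotation(
        protein_id=protein_id,
        sequence=match.group("seq"),
        start=int(start) if start is not None else None,
        end=int(end) if end is not None else None,
    )
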