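"""Reading coding sequences, qualification criteria, and translation.

A coding sequence (CDS) qualifies for codon-usage analysis when its length is
a multiple of three and at least ``min_len`` nucleotides (150 by default),
it contains no ambiguity codes, and no in-frame stop codon occurs before the
final codon.  A stop codon in the final position is allowed and is excluded
from every downstream codon statistic, so that composition, RSCU and CAI all
operate on the identical amino-acid-coding codon set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import CODON_TO_AA, STOP_CODONS

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 150

_VALID_CHARS = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """A (possibly not yet validated) coding DNA sequence.

    The sequence is normalized on construction: upper-case, U -> T.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper().replace("U", "T"))

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        """Frame-0 non-overlapping triplets (including a trailing stop)."""
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - 2, 3)]

    def effective_seq(self) -> str:
        """The sequence with a trailing stop codon (if any) removed."""
        if len(self.seq) >= 3 and len(self.seq) % 3 == 0:
            if self.seq[-3:] in STOP_CODONS:
                return self.seq[:-3]
        return self.seq


#: QC failure codes
NOT_TRIPLET = "NOT_TRIPLET"
INTERNAL_STOP = "INTERNAL_STOP"
AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
TOO_SHORT = "TOO_SHORT"
EMPTY = "EMPTY"


@dataclass(frozen=True)
class QCReport:
    id: str
    reasons: tuple[str, ...] = field(default=())

    @property
    def passed(self) -> bool:
        return not self.reasons


def effective_sequence(record: Union[str, CodingSequence]) -> str:
    """Coerce a record or raw string to the stop-trimmed analysis sequence."""
    if not isinstance(record, CodingSequence):
        record = CodingSequence(id="", seq=record)
    return record.effective_seq()


def read_fasta(path: Union[str, Path]) -> list[CodingSequence]:
    """Read a (multi-)FASTA file into unvalidated :class:`CodingSequence`.

    Record order is preserved; ids are the header up to the first whitespace;
    duplicate ids receive a numeric suffix with a logged warning.
    """
    path = Path(path)
    records: list[CodingSequence] = []
    seen: dict[str, int] = {}
    with path.open() as handle:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if first and not first.startswith(">"):
            raise ValueError(
                f"{path}: malformed FASTA, sequence data before first header"
            )
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            rid = rec.id
            if rid in seen:
                seen[rid] += 1
                new_id = f"{rid}_{seen[rid]}"
                logger.warning("duplicate FASTA id %r renamed to %r", rid, new_id)
                rid = new_id
            else:
                seen[rid] = 0
            records.append(CodingSequence(id=rid, seq=str(rec.seq)))
    return records


def write_fasta(records: Iterable[CodingSequence], path: Union[str, Path]) -> None:
    """Write records to FASTA (60-column wrapped)."""
    with Path(path).open("w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                out.write(rec.seq[i : i + 60] + "\n")


def qc_filter(record: CodingSequence, min_len: int = DEFAULT_MIN_LEN) -> QCReport:
    """Run every qualification check and report all violations.

    Checks do not short-circuit: a 151-nt sequence containing an N reports
    both ``NOT_TRIPLET`` and ``AMBIGUOUS_BASE``.  A stop codon in the final
    position is not a failure.
    """
    reasons: list[str] = []
    seq = record.seq
    if not seq:
        return QCReport(id=record.id, reasons=(EMPTY,))
    if len(seq) % 3 != 0:
        reasons.append(NOT_TRIPLET)
    if len(seq) < min_len:
        reasons.append(TOO_SHORT)
    if not _VALID_CHARS.issuperset(seq):
        reasons.append(AMBIGUOUS_BASE)
    if len(seq) % 3 == 0 and _VALID_CHARS.issuperset(seq):
        internal = record.codons()[:-1]
        if any(c in STOP_CODONS for c in internal):
            reasons.append(INTERNAL_STOP)
    return QCReport(id=record.id, reasons=tuple(reasons))


def translate(record: Union[str, CodingSequence]) -> str:
    """Translate a QC-passed CDS with the standard genetic code.

    The trailing stop codon is dropped; an internal stop raises ValueError.
    """
    seq = record.seq if isinstance(record, CodingSequence) else CodingSequence("", record).seq
    protein = str(Seq(seq).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon in {getattr(record, 'id', '<seq>')}")
    return protein


def qc_report_table(reports: Iterable[QCReport]):
    """QC reports as a pandas DataFrame (columns id, passed, reasons)."""
    import pandas as pd

    rows = [
        {"id": r.id, "passed": r.passed, "reasons": ";".join(r.reasons)}
        for r in reports
    ]
    return pd.DataFrame(rows, columns=["id", "passed", "reasons"])
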