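"""Reading, quality filtering and writing of protein-coding sequences.

The filters implement the usual integrity rules for CDS-level codon-usage
work: a CDS must be longer than a minimum (default: more than 300 nt, to
keep per-gene codon frequencies out of small-sample noise), be a whole
number of codons, begin with an initiator codon, end with a terminator,
contain no internal stop, contain no ambiguity codes, and not duplicate an
earlier sequence.  Failures are classifications, not exceptions: every
input record ends up in either the retained or the rejected list, each
rejected record carrying machine-readable reason codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Set, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counts import CodonCountTable
from .genetic_code import GeneticCode, default_code

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

# reason codes used in qc_flags / rejection logs
AMBIGUOUS_BASE = "ambiguous_base"
NOT_MULTIPLE_OF_3 = "not_multiple_of_3"
TOO_SHORT = "too_short"
MISSING_START = "missing_start"
MISSING_STOP = "missing_stop"
INTERNAL_STOP = "internal_stop"
DUPLICATE = "duplicate"


@dataclass
class CodingSequence:
    """One CDS record: id, description, uppercase nucleotide sequence and
    the set of QC reason codes accumulated so far (empty = clean)."""

    id: str
    seq: str
    description: str = ""
    qc_flags: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if not set(self.seq) <= _VALID_BASES:
            self.qc_flags.add(AMBIGUOUS_BASE)

    def __len__(self) -> int:
        return len(self.seq)

    def codons(self) -> List[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - 2, 3)]


@dataclass(frozen=True)
class FilterConfig:
    """CDS retention rules.

    ``min_length_nt`` defaults to 301: strictly more than 300 nucleotides,
    measured on the full CDS including its stop codon.
    """

    min_length_nt: int = 301
    require_start: bool = True
    require_terminal_stop: bool = True
    reject_internal_stop: bool = True
    dedupe: str = "exact_sequence"  # or "off"

    def __post_init__(self) -> None:
        if self.min_length_nt < 3:
            raise ValueError("min_length_nt must be >= 3")
        if self.dedupe not in ("exact_sequence", "off"):
            raise ValueError(f"unknown dedupe mode {self.dedupe!r}")


def read_fasta(path: str | Path) -> List[CodingSequence]:
    """Parse a nucleotide multi-FASTA into :class:`CodingSequence` records.

    Order is preserved, sequences are uppercased, and no filtering is
    applied; records containing ambiguity codes are returned with the
    ``ambiguous_base`` flag already set.
    """
    path = Path(path)
    records = [
        CodingSequence(id=rec.id, description=rec.description, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
        if len(rec.seq) > 0
    ]
    if not records:
        logger.warning("no FASTA records parsed from %s", path)
    return records


def write_fasta(records: Iterable[CodingSequence], path: str | Path) -> None:
    """Write records to FASTA (sequence on a single line per record)."""
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta-2line")


def _qc_reasons(
    record: CodingSequence, config: FilterConfig, code: GeneticCode
) -> Set[str]:
    reasons: Set[str] = set(record.qc_flags)
    seq = record.seq
    if len(seq) < config.min_length_nt:
        reasons.add(TOO_SHORT)
    if len(seq) % 3:
        reasons.add(NOT_MULTIPLE_OF_3)
        return reasons  # codon-level checks need a frame
    if AMBIGUOUS_BASE in reasons:
        return reasons  # codon-level checks need clean bases
    codons = record.codons()
    if config.require_start and codons[0] not in code.start_codons:
        reasons.add(MISSING_START)
    if config.require_terminal_stop and codons[-1] not in code.stop_codons:
        reasons.add(MISSING_STOP)
    if config.reject_internal_stop and any(
        c in code.stop_codons for c in codons[:-1]
    ):
        reasons.add(INTERNAL_STOP)
    return reasons


def filter_cds(
    records: Sequence[CodingSequence],
    config: FilterConfig | None = None,
    code: GeneticCode | None = None,
) -> Tuple[List[CodingSequence], List[CodingSequence]]:
    """Partition ``records`` into (retained, rejected).

    Every rejected record carries at least one reason code in
    ``qc_flags``; retained records have empty ``qc_flags``.  Duplicates
    (exact full-sequence identity against an earlier *retained* record)
    are rejected with reason ``duplicate``; the first occurrence is kept.
    """
    config = config or FilterConfig()
    code = code or default_code()
    retained: List[CodingSequence] = []
    rejected: List[CodingSequence] = []
    seen: Set[str] = set()
    for record in records:
        reasons = _qc_reasons(record, config, code)
        if not reasons and config.dedupe == "exact_sequence":
            if record.seq in seen:
                reasons.add(DUPLICATE)
                logger.info("duplicate sequence rejected: %s", record.id)
        if reasons:
            rejected.append(
                CodingSequence(record.id, record.seq, record.description, reasons)
            )
        else:
            seen.add(record.seq)
            retained.append(
                CodingSequence(record.id, record.seq, record.description, set())
            )
    return retained, rejected


def write_rejection_log(rejected: Sequence[CodingSequence], path: str | Path) -> None:
    """TSV rejection log: id <tab> comma-joined sorted reason codes."""
    with open(path, "w") as handle:
        handle.write("id\treasons\n")
        for record in rejected:
            handle.write(f"{record.id}\t{','.join(sorted(record.qc_flags))}\n")


def codon_counts(
    seq: CodingSequence | str,
    code: GeneticCode | None = None,
    include_stops: bool = True,
) -> CodonCountTable:
    """Codon counts of a QC-passed CDS (length must be a multiple of 3)."""
    code = code or default_code()
    if isinstance(seq, CodingSequence):
        return CodonCountTable.from_sequence(
            seq.seq, source_id=seq.id, include_stops=include_stops, code=code
        )
    return CodonCountTable.from_sequence(
        seq, include_stops=include_stops, code=code
    )
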