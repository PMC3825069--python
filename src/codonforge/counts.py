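"""Codon count tables for single genes and pooled gene sets."""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, Mapping, Sequence, Tuple

from .exceptions import FrameError, UndefinedStatisticError
from .genetic_code import ALL_CODONS, GeneticCode


class CodonCountTable:
    """Counts over the 64 codons for one gene or a pooled gene set.

    Counts are kept for all codons (stops included); statistics that are
    sense-only restrict themselves via the :class:`GeneticCode`.
    """

    __slots__ = ("_counts", "source_ids")

    def __init__(
        self,
        counts: Mapping[str, int] | None = None,
        source_ids: Sequence[str] = (),
    ) -> None:
        self._counts: Dict[str, int] = dict.fromkeys(ALL_CODONS, 0)
        if counts:
            for codon, n in counts.items():
                codon = codon.upper()
                if codon not in self._counts:
                    raise KeyError(f"not a DNA codon: {codon!r}")
                if n < 0:
                    raise ValueError(f"negative count for {codon}: {n}")
                self._counts[codon] = int(n)
        self.source_ids: Tuple[str, ...] = tuple(source_ids)

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_sequence(
        cls, seq: str, source_id: str = "", include_stops: bool = True,
        code: GeneticCode | None = None,
    ) -> "CodonCountTable":
        """Count codons of ``seq`` read in frame from position 0.

        ``include_stops=False`` drops stop-codon occurrences (requires
        ``code``).  Raises :class:`FrameError` if the length is not a
        multiple of 3.
        """
        seq = seq.upper()
        if len(seq) == 0 or len(seq) % 3:
            raise FrameError(
                f"sequence length {len(seq)} is not a positive multiple of 3"
            )
        counts: Dict[str, int] = {}
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon not in ALL_CODONS:
                raise ValueError(f"non-ACGT codon {codon!r} at position {i}")
            counts[codon] = counts.get(codon, 0) + 1
        table = cls(counts, source_ids=(source_id,) if source_id else ())
        if not include_stops:
            if code is None:
                raise ValueError("include_stops=False requires a GeneticCode")
            table = table.without_stops(code)
        return table

    @classmethod
    def pool(cls, tables: Iterable["CodonCountTable"]) -> "CodonCountTable":
        """Element-wise sum of several tables; source ids concatenate."""
        pooled = dict.fromkeys(ALL_CODONS, 0)
        ids: list = []
        for t in tables:
            for codon, n in t._counts.items():
                pooled[codon] += n
            ids.extend(t.source_ids)
        return cls(pooled, source_ids=ids)

    # -- views -----------------------------------------------------------

    def without_stops(self, code: GeneticCode) -> "CodonCountTable":
        counts = {
            c: n for c, n in self._counts.items() if c not in code.stop_codons
        }
        return CodonCountTable(counts, source_ids=self.source_ids)

    def as_dict(self) -> Dict[str, int]:
        return dict(self._counts)

    # -- totals ----------------------------------------------------------

    def total(self) -> int:
        return sum(self._counts.values())

    def sense_total(self, code: GeneticCode) -> int:
        return sum(self._counts[c] for c in code.sense_codons)

    def family_total(self, codons: Sequence[str]) -> int:
        return sum(self._counts[c] for c in codons)

    def require_nonempty(self, code: GeneticCode | None = None) -> None:
        total = self.sense_total(code) if code is not None else self.total()
        if total == 0:
            raise UndefinedStatisticError("empty codon count table")

    # -- dunder ----------------------------------------------------------

    def __getitem__(self, codon: str) -> int:
        return self._counts[codon.upper()]

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable.pool([self, other])

    def __iter__(self) -> Iterator[str]:
        return iter(ALL_CODONS)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonCountTable):
            return NotImplemented
        return self._counts == other._counts

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nz = {c: n for c, n in self._counts.items() if n}
        return f"CodonCountTable(total={self.total()}, nonzero={len(nz)})"
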