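"""Genetic-code tables and synonymous-family structure.

The default is the bacterial/archaeal/plastid code (NCBI translation
table 11), which is the appropriate table for cyanobacteria and for
plastid-like organelle genomes such as the *Paulinella chromatophora*
chromatophore.  Codon-to-amino-acid maps are taken from
:mod:`Bio.Data.CodonTable`; this module adds the synonymous-family view
(which codons are interchangeable, family degeneracy, fourfold boxes)
that every codon-usage statistic needs.
"""

from __future__ import annotations

from functools import cached_property
from typing import Dict, FrozenSet, Iterable, Mapping, Tuple

from Bio.Data import CodonTable

#: Single-character symbol used for termination (stop) "amino acid".
STOP = "*"

BASES = ("A", "C", "G", "T")

#: All 64 codons in fixed alphabetical order.
ALL_CODONS: Tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

#: Conventional start-codon set for bacterial CDS annotation.  NCBI table 11
#: formally allows more initiators (ATT/ATC/ATA/CTG) but annotated bacterial
#: CDS overwhelmingly begin with one of these three.
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})


class GeneticCode:
    """A codon table plus the synonymous-family structure derived from it.

    Parameters
    ----------
    codon_to_aa
        Mapping of all 64 codons to one-letter amino acids, with stop
        codons mapped to :data:`STOP`.
    start_codons, stop_codons
        Sets of permitted initiator and terminator codons.
    name
        Human-readable label for reports.
    """

    def __init__(
        self,
        codon_to_aa: Mapping[str, str],
        start_codons: Iterable[str],
        stop_codons: Iterable[str],
        name: str = "custom",
    ) -> None:
        if set(codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon_to_aa must cover all 64 codons")
        self.codon_to_aa: Dict[str, str] = {c: codon_to_aa[c] for c in ALL_CODONS}
        self.start_codons: FrozenSet[str] = frozenset(start_codons)
        self.stop_codons: FrozenSet[str] = frozenset(stop_codons)
        self.name = name
        for s in self.stop_codons:
            if self.codon_to_aa[s] != STOP:
                raise ValueError(f"stop codon {s} not mapped to {STOP!r}")

    @classmethod
    def from_ncbi_id(
        cls,
        table_id: int = 11,
        start_codons: Iterable[str] | None = DEFAULT_START_CODONS,
    ) -> "GeneticCode":
        """Build a :class:`GeneticCode` from an NCBI translation-table id.

        ``start_codons=None`` keeps the NCBI table's full initiator set;
        the default restricts to the conventional bacterial {ATG, GTG, TTG}.
        """
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for s in table.stop_codons:
            mapping[s] = STOP
        starts = table.start_codons if start_codons is None else start_codons
        return cls(mapping, starts, table.stop_codons, name=f"NCBI table {table_id}")

    # -- family structure ------------------------------------------------

    @cached_property
    def sense_codons(self) -> Tuple[str, ...]:
        """The 61 codons that encode an amino acid, alphabetical order."""
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP)

    @cached_property
    def families(self) -> Dict[str, Tuple[str, ...]]:
        """Amino acid -> tuple of synonymous sense codons (partitions the
        sense codons; stops are not included)."""
        fams: Dict[str, list] = {}
        for codon in self.sense_codons:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        return {aa: tuple(codons) for aa, codons in fams.items()}

    @cached_property
    def degeneracy(self) -> Dict[str, int]:
        """Amino acid -> number of synonymous codons."""
        return {aa: len(codons) for aa, codons in self.families.items()}

    @cached_property
    def synonymous_codons(self) -> Tuple[str, ...]:
        """Sense codons whose amino acid has >= 2 synonymous codons.

        Under table 11 these are the 59 codons used for RSCU vectors and
        silent-site composition (ATG and TGG excluded).
        """
        return tuple(
            c for c in self.sense_codons if self.degeneracy[self.codon_to_aa[c]] >= 2
        )

    @cached_property
    def fourfold_boxes(self) -> Tuple[str, ...]:
        """Dinucleotide prefixes whose four codons all encode one amino acid.

        Under table 11: GC, CG, GG, CT, CC, TC, AC, GT — the eight boxes
        used for parity-rule-2 analysis.
        """
        boxes = []
        for a in BASES:
            for b in BASES:
                quartet = [a + b + n for n in BASES]
                aas = {self.codon_to_aa[c] for c in quartet}
                if len(aas) == 1 and STOP not in aas:
                    boxes.append(a + b)
        return tuple(boxes)

    def family_of(self, codon: str) -> Tuple[str, ...]:
        """Synonymous codons of ``codon`` (including itself); stop codons
        form their own family."""
        aa = self.codon_to_aa[codon]
        if aa == STOP:
            return tuple(sorted(self.stop_codons))
        return self.families[aa]

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneticCode({self.name!r}, starts={sorted(self.start_codons)})"


def default_code() -> GeneticCode:
    """The package default: translation table 11 with {ATG, GTG, TTG} starts."""
    return GeneticCode.from_ncbi_id(11)
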