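"""Nucleotide composition: overall, positional and silent-site.

Conventions
-----------
* Overall A/T/G/C fractions and positional GC are computed over *sense*
  codons only; stop codons are excluded because every downstream index is
  sense-codon based.
* "GC3" in reports means ``gc3s``: G+C at third positions of codons whose
  amino acid has at least two synonymous codons (Met, Trp and stops
  excluded).  This is the CodonW convention; the plain third-position GC
  over all sense codons is exposed alongside as ``gc3_all``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .counts import CodonCountTable
from .exceptions import UndefinedStatisticError
from .genetic_code import GeneticCode


@dataclass(frozen=True)
class CompositionProfile:
    """Per-gene (or pooled) composition summary.

    All values are fractions in [0, 1].  ``gc3s = g3 + c3`` is the
    silent-site GC used as "GC3" throughout; ``gc12 = (gc1 + gc2) / 2``.
    """

    frac_a: float
    frac_t: float
    frac_g: float
    frac_c: float
    gc: float
    gc1: float
    gc2: float
    gc3_all: float
    gc12: float
    a3: float
    t3: float
    g3: float
    c3: float
    gc3s: float


def _base_tallies(counts: CodonCountTable, codons) -> Tuple[dict, dict, dict]:
    """Per-position base tallies over the given codons (weighted by count)."""
    pos = [dict.fromkeys("ACGT", 0) for _ in range(3)]
    for codon in codons:
        n = counts[codon]
        if n:
            for k in range(3):
                pos[k][codon[k]] += n
    return pos[0], pos[1], pos[2]


def base_composition(
    counts: CodonCountTable, code: GeneticCode
) -> Tuple[float, float, float, float, float]:
    """(frac_A, frac_T, frac_G, frac_C, gc) over all bases of sense codons."""
    counts.require_nonempty(code)
    p1, p2, p3 = _base_tallies(counts, code.sense_codons)
    tot = {b: p1[b] + p2[b] + p3[b] for b in "ACGT"}
    n = sum(tot.values())
    fa, ft, fg, fc = (tot[b] / n for b in "ATGC")
    return fa, ft, fg, fc, fg + fc


def positional_gc(
    counts: CodonCountTable, code: GeneticCode
) -> Tuple[float, float, float, float]:
    """(gc1, gc2, gc3_all, gc12) over sense codons."""
    counts.require_nonempty(code)
    tallies = _base_tallies(counts, code.sense_codons)
    gcs = []
    for tally in tallies:
        n = sum(tally.values())
        gcs.append((tally["G"] + tally["C"]) / n)
    gc1, gc2, gc3_all = gcs
    return gc1, gc2, gc3_all, (gc1 + gc2) / 2.0


def silent_base_composition(
    counts: CodonCountTable, code: GeneticCode
) -> Tuple[float, float, float, float, float]:
    """(a3, t3, g3, c3, gc3s) at third positions of synonymous codons.

    Restricted to codons of amino acids with degeneracy >= 2 (Met, Trp and
    stop codons excluded).  Raises :class:`UndefinedStatisticError` when no
    such codon is present.
    """
    _, _, p3 = _base_tallies(counts, code.synonymous_codons)
    n = sum(p3.values())
    if n == 0:
        raise UndefinedStatisticError(
            "no codons from synonymous families; silent composition undefined"
        )
    a3, t3, g3, c3 = (p3[b] / n for b in "ATGC")
    return a3, t3, g3, c3, g3 + c3


def composition_profile(
    counts: CodonCountTable, code: GeneticCode
) -> CompositionProfile:
    """Full :class:`CompositionProfile` for one count table."""
    fa, ft, fg, fc, gc = base_composition(counts, code)
    gc1, gc2, gc3_all, gc12 = positional_gc(counts, code)
    a3, t3, g3, c3, gc3s = silent_base_composition(counts, code)
    return CompositionProfile(
        frac_a=fa, frac_t=ft, frac_g=fg, frac_c=fc, gc=gc,
        gc1=gc1, gc2=gc2, gc3_all=gc3_all, gc12=gc12,
        a3=a3, t3=t3, g3=g3, c3=c3, gc3s=gc3s,
    )
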