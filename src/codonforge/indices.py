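"""Codon-usage indices: RSCU, ENC, CAI, SCUO, GRAVY and aromaticity.

Definitions
-----------
RSCU (relative synonymous codon usage)
    For codon *j* of an amino acid with *k* synonymous codons and family
    total *n*: ``RSCU = k * x_j / n``.  1 means no bias; family absent
    yields NaN (undefined), never 0.

ENC (effective number of codons, Wright)
    ``Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6`` under the standard code, where
    the class terms are the code's family counts per degeneracy and
    ``Fk`` averages the family homozygosity estimator
    ``F = (n * sum(p_j^2) - 1) / (n - 1)`` over estimable families of
    degeneracy *k*.  Ranges from 20 (one codon per amino acid) to 61;
    values beyond 61 produced by very even usage are clamped to 61.

CAI (codon adaptation index, Sharp & Li)
    Relative adaptiveness ``w = x / max(x)`` within each family of a
    pooled highly-expressed reference set (zero-count codons floored);
    a gene's CAI is the geometric mean of *w* over its codons, Met/Trp
    and stops excluded.

SCUO (synonymous codon usage order)
    Information-theoretic orderliness: per family,
    ``O = (ln k - H) / ln k`` with Shannon entropy *H* in nats; the gene
    value is the codon-share-weighted mean of *O* over observed families
    of degeneracy >= 2.  0 = uniform usage, 1 = one codon per family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .composition import composition_profile
from .counts import CodonCountTable
from .exceptions import UndefinedStatisticError
from .genetic_code import STOP, GeneticCode

logger = logging.getLogger(__name__)

AROMATIC_RESIDUES = frozenset("FYW")


def rscu(
    counts: CodonCountTable, code: GeneticCode, include_stops: bool = False
) -> Dict[str, float]:
    """RSCU per codon; families with zero total map to NaN.

    ``include_stops=True`` adds the stop codons as one extra family (used
    for the published-style pooled usage tables that carry TER rows).
    """
    counts.require_nonempty(code)
    families: List[Sequence[str]] = list(code.families.values())
    if include_stops:
        families.append(sorted(code.stop_codons))
    out: Dict[str, float] = {}
    for family in families:
        k = len(family)
        n = counts.family_total(family)
        for codon in family:
            out[codon] = k * counts[codon] / n if n else math.nan
    return out


def _family_homozygosity(counts: CodonCountTable, family: Sequence[str]):
    """Wright's F-hat for one family, or None when not estimable (n <= 1,
    or F = 0 which would break the harmonic average)."""
    n = counts.family_total(family)
    if n <= 1:
        return None
    s = sum((counts[c] / n) ** 2 for c in family)
    f_hat = (n * s - 1.0) / (n - 1.0)
    return f_hat if f_hat > 0 else None


def enc(counts: CodonCountTable, code: GeneticCode, clamp: bool = True) -> float:
    """Wright's effective number of codons for one gene.

    Unobserved degeneracy classes are imputed: the 3-fold class (Ile) as
    the mean of the 2- and 4-fold class averages, any other missing class
    as the mean of the defined class averages.  Raises
    :class:`UndefinedStatisticError` when no family at all is estimable.
    """
    by_k: Dict[int, List[Sequence[str]]] = {}
    for family in code.families.values():
        by_k.setdefault(len(family), []).append(family)

    f_means: Dict[int, float] = {}
    for k, fams in by_k.items():
        if k == 1:
            continue
        f_hats = [f for f in map(lambda fam: _family_homozygosity(counts, fam), fams)
                  if f is not None]
        if f_hats:
            f_means[k] = float(np.mean(f_hats))
    if not f_means:
        raise UndefinedStatisticError("no synonymous family estimable; ENC undefined")

    nc = float(len(by_k.get(1, ())))  # single-codon families contribute 1 each
    for k, fams in sorted(by_k.items()):
        if k == 1:
            continue
        if k in f_means:
            f_bar = f_means[k]
        elif k == 3 and 2 in f_means and 4 in f_means:
            f_bar = (f_means[2] + f_means[4]) / 2.0
        else:
            f_bar = float(np.mean(list(f_means.values())))
        nc += len(fams) / f_bar
    if clamp and nc > 61.0:
        logger.debug("ENC %.3f clamped to 61 (ids=%s)", nc, counts.source_ids)
        nc = 61.0
    return nc


@dataclass(frozen=True)
class CAIWeights:
    """Relative-adaptiveness weights; each family's maximum is 1."""

    w: Mapping[str, float]
    reference_ids: Sequence[str] = field(default_factory=tuple)
    floor: float = 0.01


def cai_weights(
    reference: Iterable[CodonCountTable],
    code: GeneticCode,
    floor: float = 0.01,
) -> CAIWeights:
    """Pool the reference tables and derive w = x / max(x) per family.

    Zero-count codons receive ``floor`` instead of 0 so that genes using
    them keep a finite CAI.  Met, Trp and stops are excluded.
    """
    tables = list(reference)
    if not tables:
        raise UndefinedStatisticError("empty CAI reference set")
    pooled = CodonCountTable.pool(tables)
    weights: Dict[str, float] = {}
    for family in code.families.values():
        if len(family) < 2:
            continue
        x_max = max(pooled[c] for c in family)
        for codon in family:
            if x_max == 0:
                weights[codon] = floor
            else:
                weights[codon] = max(pooled[codon] / x_max, floor)
    return CAIWeights(w=weights, reference_ids=pooled.source_ids, floor=floor)


def cai(counts: CodonCountTable, weights: CAIWeights) -> float:
    """Geometric mean of weights over the gene's eligible codons, computed
    in log space."""
    log_sum = 0.0
    n = 0
    for codon, w in weights.w.items():
        x = counts[codon]
        if x:
            log_sum += x * math.log(w)
            n += x
    if n == 0:
        raise UndefinedStatisticError("no codons eligible for CAI")
    return math.exp(log_sum / n)


def scuo(counts: CodonCountTable, code: GeneticCode) -> float:
    """Synonymous codon usage order in [0, 1] (natural logs)."""
    family_stats = []  # (n_i, O_i)
    for family in code.families.values():
        k = len(family)
        if k < 2:
            continue
        n = counts.family_total(family)
        if n == 0:
            continue
        h = 0.0
        for codon in family:
            p = counts[codon] / n
            if p > 0:
                h -= p * math.log(p)
        family_stats.append((n, (math.log(k) - h) / math.log(k)))
    if not family_stats:
        raise UndefinedStatisticError("no synonymous family observed; SCUO undefined")
    total = sum(n for n, _ in family_stats)
    value = sum(n / total * o for n, o in family_stats)
    return min(max(value, 0.0), 1.0)


def _residue_counts(counts: CodonCountTable, code: GeneticCode) -> Dict[str, int]:
    residues: Dict[str, int] = {}
    for codon in code.sense_codons:
        n = counts[codon]
        if n:
            aa = code.codon_to_aa[codon]
            residues[aa] = residues.get(aa, 0) + n
    if not residues:
        raise UndefinedStatisticError("empty translation")
    return residues


def gravy(counts: CodonCountTable, code: GeneticCode) -> float:
    """Mean Kyte-Doolittle hydropathy of the translated protein."""
    residues = _residue_counts(counts, code)
    total = sum(residues.values())
    return sum(KYTE_DOOLITTLE[aa] * n for aa, n in residues.items()) / total


def aromaticity(counts: CodonCountTable, code: GeneticCode) -> float:
    """Fraction of residues that are Phe, Tyr or Trp."""
    residues = _residue_counts(counts, code)
    total = sum(residues.values())
    return sum(n for aa, n in residues.items() if aa in AROMATIC_RESIDUES) / total


def aggregate_usage_table(
    genes: Iterable[CodonCountTable], code: GeneticCode
) -> pd.DataFrame:
    """Pooled codon usage in published-table layout.

    Columns: ``amino_acid`` (one-letter, ``TER`` for stops), ``codon``,
    ``n`` (pooled count), ``rscu`` (pooled RSCU, stops as their own
    family).  Rows are ordered by amino acid then codon.
    """
    pooled = CodonCountTable.pool(genes)
    pooled.require_nonempty(code)
    values = rscu(pooled, code, include_stops=True)
    rows = []
    for aa in sorted(code.families):
        for codon in code.families[aa]:
            rows.append((aa, codon, pooled[codon], values[codon]))
    for codon in sorted(code.stop_codons):
        rows.append(("TER", codon, pooled[codon], values[codon]))
    return pd.DataFrame(rows, columns=["amino_acid", "codon", "n", "rscu"])


def gene_index_table(
    genes: Sequence, code: GeneticCode, weights: CAIWeights
) -> pd.DataFrame:
    """Per-gene index table for a list of (id, CodonCountTable) pairs or
    objects with ``.source_ids``.

    Columns: id, length_codons (sense codons), enc, cai, scuo, gravy,
    aromaticity and the full composition profile (GC3 = silent-site GC).
    """
    rows = []
    for item in genes:
        if isinstance(item, tuple):
            gene_id, table = item
        else:
            table = item
            gene_id = table.source_ids[0] if table.source_ids else ""
        sense = table.without_stops(code)
        profile = composition_profile(sense, code)
        rows.append({
            "id": gene_id,
            "length_codons": sense.sense_total(code),
            "enc": enc(sense, code),
            "cai": cai(sense, weights),
            "scuo": scuo(sense, code),
            "gravy": gravy(sense, code),
            "aromaticity": aromaticity(sense, code),
            "a": profile.frac_a, "t": profile.frac_t,
            "g": profile.frac_g, "c": profile.frac_c,
            "gc": profile.gc, "gc1": profile.gc1, "gc2": profile.gc2,
            "gc3": profile.gc3s, "gc12": profile.gc12,
            "a3": profile.a3, "t3": profile.t3,
            "g3": profile.g3, "c3": profile.c3,
        })
    return pd.DataFrame(rows).set_index("id")
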