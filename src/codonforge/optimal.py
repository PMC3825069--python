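"""Putative optimal codon detection by 2x2 chi-square on axis extremes.

Genes at the two extremes of correspondence-analysis axis 1 (default:
5% per side) are pooled, and for each sense codon a 2x2 contingency
table is formed — [codon count, count of its synonymous alternatives]
across [high-bias group, low-bias group].  A codon is called a putative
optimal codon when the chi-square (df=1, no continuity correction) is
significant and its RSCU is higher in the high-bias group.  Because CA
axis signs are arbitrary, the high-bias side is anchored externally
(conventionally, the extreme with the lower mean ENC).
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CodonCountTable
from .exceptions import UndefinedStatisticError
from .genetic_code import GeneticCode
from .indices import rscu


def extreme_gene_sets(
    coords: pd.Series, fraction: float = 0.05
) -> Tuple[List[str], List[str]]:
    """(left ids, right ids): the floor(fraction*N) genes at each end of
    an axis-coordinate series.  Disjoint by construction; raises when a
    set would be empty."""
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    n = len(coords)
    k = math.floor(fraction * n)
    if k < 1:
        raise UndefinedStatisticError(
            f"{n} genes give empty {fraction:.0%} extreme sets"
        )
    ordered = coords.sort_values(kind="mergesort")
    left = list(ordered.index[:k])
    right = list(ordered.index[-k:])
    return left, right


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square for [[a, b], [c, d]], df=1, no Yates correction."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    return n * (a * d - b * c) ** 2 / denom


def chi2_optimal_codons(
    high: CodonCountTable,
    low: CodonCountTable,
    code: GeneticCode,
    alpha: float = 0.05,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-codon chi-square contrast between pooled high-bias and
    low-bias gene sets.

    Returns a DataFrame over the sense codons with synonymous
    alternatives: amino_acid, codon, the 2x2 cells (count_high,
    syn_high, count_low, syn_low), chi2, p, RSCU in each pool,
    direction ("over_in_high" / "over_in_low" / "none") and the
    ``optimal`` flag (significant and over-represented in the
    high-bias pool).  Codons whose family is absent from either pool
    are reported with NaN statistics and never flagged.
    """
    high.require_nonempty(code)
    low.require_nonempty(code)
    rscu_high = rscu(high, code)
    rscu_low = rscu(low, code)
    rows = []
    for aa in sorted(code.families):
        family = code.families[aa]
        if len(family) < 2:
            continue
        fam_high = high.family_total(family)
        fam_low = low.family_total(family)
        for codon in family:
            a = high[codon]
            b = fam_high - a
            c = low[codon]
            d = fam_low - c
            if fam_high == 0 or fam_low == 0:
                chi2 = p = math.nan
            elif yates:
                n = a + b + c + d
                denom = (a + b) * (c + d) * (a + c) * (b + d)
                chi2 = (
                    n * (abs(a * d - b * c) - n / 2.0) ** 2 / denom
                    if denom else math.nan
                )
                p = stats.chi2.sf(chi2, 1) if chi2 == chi2 else math.nan
            else:
                chi2 = _chi2_2x2(a, b, c, d)
                p = stats.chi2.sf(chi2, 1) if chi2 == chi2 else math.nan
            rh, rl = rscu_high[codon], rscu_low[codon]
            if p == p and p <= alpha:
                direction = "over_in_high" if rh > rl else "over_in_low"
            else:
                direction = "none"
            rows.append({
                "amino_acid": aa, "codon": codon,
                "count_high": a, "syn_high": b,
                "count_low": c, "syn_low": d,
                "chi2": chi2, "p": p,
                "rscu_high": rh, "rscu_low": rl,
                "direction": direction,
                "optimal": direction == "over_in_high",
            })
    return pd.DataFrame(rows)


def detect_optimal_codons(
    gene_tables: Sequence[CodonCountTable],
    coords: pd.Series,
    enc_values: pd.Series,
    code: GeneticCode,
    fraction: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """End-to-end optimal-codon detection for genes with axis-1
    coordinates and per-gene ENC.

    The axis extreme with the lower mean ENC is taken as the high-bias
    pool.  ``gene_tables`` must align with ``coords``'s index.
    """
    by_id = {}
    for table, gene_id in zip(gene_tables, coords.index):
        by_id[gene_id] = table
    left_ids, right_ids = extreme_gene_sets(coords, fraction)
    left = CodonCountTable.pool(by_id[g] for g in left_ids)
    right = CodonCountTable.pool(by_id[g] for g in right_ids)
    if enc_values.loc[left_ids].mean() <= enc_values.loc[right_ids].mean():
        high, low = left, right
    else:
        high, low = right, left
    return chi2_optimal_codons(high, low, code, alpha=alpha)
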