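"""Correspondence analysis (CA) on the gene x 59-codon RSCU matrix.

Each gene is a 59-dimensional vector of RSCU values over the sense
codons that have synonymous alternatives (Met, Trp and stops excluded).
Standard CA is applied: divide by the grand total, form the
standardized residual matrix S = D_r^{-1/2} (P - r c^T) D_c^{-1/2},
take its SVD, and report axis inertias (squared singular values) and
principal coordinates for genes (rows) and codons (columns).

Axis signs are arbitrary in CA; for reproducibility each axis is
oriented so that its gene coordinates correlate non-negatively with
silent-site GC (GC3s) when an anchor is supplied, falling back to a
positive first-codon loading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from .counts import CodonCountTable
from .exceptions import UndefinedStatisticError
from .genetic_code import GeneticCode
from .indices import rscu
from .diagnostics import spearman

logger = logging.getLogger(__name__)


def build_rscu_matrix(
    genes: Sequence[CodonCountTable],
    code: GeneticCode,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene x 59 RSCU matrix (rows: genes, columns: synonymous codons in
    fixed alphabetical order).  Undefined RSCU entries (family unobserved
    in a gene) are imputed as 0 and logged."""
    if len(genes) < 2:
        raise UndefinedStatisticError("correspondence analysis needs >= 2 genes")
    codons = list(code.synonymous_codons)
    if gene_ids is None:
        gene_ids = [
            t.source_ids[0] if t.source_ids else f"gene{i}"
            for i, t in enumerate(genes)
        ]
    rows = []
    for gene_id, table in zip(gene_ids, genes):
        values = rscu(table, code)
        row = [values[c] for c in codons]
        n_missing = sum(1 for v in row if v != v)  # NaN check
        if n_missing:
            logger.debug("%s: %d undefined RSCU entries imputed as 0",
                         gene_id, n_missing)
        rows.append([0.0 if v != v else v for v in row])
    return pd.DataFrame(rows, index=pd.Index(gene_ids, name="id"), columns=codons)


@dataclass
class COAResult:
    """CA decomposition: per-axis inertia fractions (of the total over all
    non-null axes), principal coordinates, and the total inertia
    (= chi-square statistic of the matrix / grand total)."""

    inertia: np.ndarray            # sigma_k^2 for retained axes
    inertia_fractions: np.ndarray  # share of total inertia, retained axes
    total_inertia: float
    gene_coords: pd.DataFrame      # genes x retained axes
    codon_coords: pd.DataFrame     # 59 x retained axes (NaN for dropped cols)
    row_masses: pd.Series

    @property
    def n_axes(self) -> int:
        return len(self.inertia)


def correspondence_analysis(
    matrix: pd.DataFrame, n_axes: int = 5
) -> COAResult:
    """Standard correspondence analysis of a non-negative matrix.

    Columns with zero total are excluded from the decomposition (their
    coordinates are reported as NaN); rows must all have positive totals.
    ``n_axes`` beyond the available rank is truncated with a warning.
    """
    m = matrix.to_numpy(dtype=float)
    if np.any(m < 0):
        raise ValueError("CA requires a non-negative matrix")
    grand = m.sum()
    if grand <= 0:
        raise UndefinedStatisticError("zero grand total: CA undefined")
    row_sums = m.sum(axis=1)
    if np.any(row_sums == 0):
        bad = matrix.index[row_sums == 0].tolist()
        raise UndefinedStatisticError(f"rows with zero total: {bad}")
    col_keep = m.sum(axis=0) > 0
    if not col_keep.all():
        logger.debug("dropping %d all-zero columns from CA",
                     int((~col_keep).sum()))
    mk = m[:, col_keep]

    p = mk / grand
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sing, vt = np.linalg.svd(s, full_matrices=False)

    max_axes = min(mk.shape) - 1
    if n_axes > max_axes:
        logger.warning("n_axes=%d exceeds available rank %d; truncating",
                       n_axes, max_axes)
        n_axes = max_axes
    inertia_all = sing ** 2
    total = float(inertia_all[:max_axes].sum())
    keep = slice(0, n_axes)

    # principal coordinates
    row_coords = (u[:, keep] * sing[keep]) / np.sqrt(r)[:, None]
    col_coords = (vt.T[:, keep] * sing[keep]) / np.sqrt(c)[:, None]

    axis_names = [f"axis{k + 1}" for k in range(n_axes)]
    gene_coords = pd.DataFrame(row_coords, index=matrix.index, columns=axis_names)
    codon_coords = pd.DataFrame(
        np.nan, index=matrix.columns, columns=axis_names, dtype=float
    )
    codon_coords.loc[matrix.columns[col_keep]] = col_coords
    fractions = inertia_all[keep] / total if total > 0 else inertia_all[keep] * 0.0
    return COAResult(
        inertia=inertia_all[keep].copy(),
        inertia_fractions=fractions,
        total_inertia=total,
        gene_coords=gene_coords,
        codon_coords=codon_coords,
        row_masses=pd.Series(r, index=matrix.index, name="mass"),
    )


def orient_axes(result: COAResult, anchor: pd.Series | None = None) -> COAResult:
    """Resolve CA sign indeterminacy in place (and return the result).

    Each axis is flipped, if needed, so that its gene coordinates have a
    non-negative Spearman correlation with ``anchor`` (typically per-gene
    GC3s); when no anchor is given, or the correlation is undefined or
    zero, the first codon's loading is made positive instead.
    """
    for axis in result.gene_coords.columns:
        sign = 0.0
        if anchor is not None:
            aligned = anchor.reindex(result.gene_coords.index)
            try:
                rho, _ = spearman(result.gene_coords[axis].to_numpy(),
                                  aligned.to_numpy())
                sign = np.sign(rho)
            except UndefinedStatisticError:
                sign = 0.0
        if sign == 0.0:
            loadings = result.codon_coords[axis].dropna()
            sign = np.sign(loadings.iloc[0]) if len(loadings) else 1.0
        if sign < 0:
            result.gene_coords[axis] *= -1.0
            result.codon_coords[axis] *= -1.0
    return result


def _correlation_table(
    coords: pd.DataFrame, frame: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho and one-tailed p between each axis and each column of
    ``frame`` (aligned on index).  Undefined correlations yield NaN."""
    columns = pd.MultiIndex.from_product([frame.columns, ("rho", "p")])
    table = pd.DataFrame(np.nan, index=coords.columns, columns=columns)
    for axis in coords.columns:
        x = coords[axis].to_numpy()
        for col in frame.columns:
            y = frame[col].to_numpy(dtype=float)
            try:
                rho, _ = spearman(x, y)
                alt = "greater" if rho >= 0 else "less"
                rho, p = spearman(x, y, alternative=alt)
            except UndefinedStatisticError:
                continue
            table.loc[axis, (col, "rho")] = rho
            table.loc[axis, (col, "p")] = p
    return table


def axis_index_correlations(
    result: COAResult, records: pd.DataFrame,
    columns: Iterable[str] = ("a3", "t3", "g3", "c3", "gc3", "enc", "cai",
                              "gravy", "aromaticity", "length_codons"),
) -> pd.DataFrame:
    """Axis-by-index Spearman table (one-tailed p in the observed
    direction), in the layout of published axis/index tables."""
    cols = [c for c in columns if c in records.columns]
    frame = records.loc[result.gene_coords.index, cols]
    return _correlation_table(result.gene_coords, frame)


def axis_codon_correlations(
    result: COAResult, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of each axis's gene coordinates with each
    codon's RSCU column; constant columns yield NaN."""
    frame = matrix.loc[result.gene_coords.index]
    return _correlation_table(result.gene_coords, frame)
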