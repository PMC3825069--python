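"""Model/Results interface over the full codon-usage analysis.

:class:`CodonUsageAnalysis` is constructed from CDS records (or a FASTA
path) plus configuration; :meth:`CodonUsageAnalysis.fit` runs quality
filtering, per-gene indices, the mutation/selection diagnostics,
correspondence analysis and optimal-codon detection, returning a
:class:`CodonUsageResults` that holds every table, offers a text
``summary()``, writes the TSV artifact set and exposes diagnostic plots.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cds_io import (
    CodingSequence, FilterConfig, codon_counts, filter_cds, read_fasta,
    write_rejection_log,
)
from .coa import (
    COAResult, axis_codon_correlations, axis_index_correlations,
    build_rscu_matrix, correspondence_analysis, orient_axes,
)
from .counts import CodonCountTable
from .diagnostics import (
    RegressionResult, enc_residuals, expected_enc, linear_fit,
    neutrality_fit, pr2_point, scuo_gc_fit, spearman,
)
from .exceptions import CodonForgeError, UndefinedStatisticError
from .genetic_code import GeneticCode, default_code
from .indices import (
    CAIWeights, aggregate_usage_table, cai_weights, gene_index_table,
)
from .optimal import detect_optimal_codons

logger = logging.getLogger(__name__)


class CodonUsageAnalysis:
    """Synonymous codon-usage analysis of a set of protein-coding genes.

    Parameters
    ----------
    records
        CDS records (unfiltered; QC runs inside :meth:`fit`).
    code
        Genetic code; defaults to NCBI table 11.
    filter_config
        CDS retention rules (default: >300 nt, start/stop/no internal
        stop, exact-duplicate removal).
    reference_pattern
        Regex matched (case-insensitively) against FASTA descriptions to
        pick the highly-expressed CAI reference set; the conventional
        choice is ribosomal-protein genes.
    reference_ids
        Explicit reference gene ids; overrides the pattern.
    n_axes, optimal_fraction, alpha
        Correspondence-analysis axes to retain, the per-side extreme
        fraction along axis 1, and the chi-square significance level for
        optimal-codon calls.
    """

    def __init__(
        self,
        records: Sequence[CodingSequence],
        code: GeneticCode | None = None,
        filter_config: FilterConfig | None = None,
        reference_pattern: str = "ribosomal protein",
        reference_ids: Sequence[str] | None = None,
        n_axes: int = 5,
        optimal_fraction: float = 0.05,
        alpha: float = 0.05,
    ) -> None:
        self.records = list(records)
        self.code = code or default_code()
        self.filter_config = filter_config or FilterConfig()
        self.reference_pattern = reference_pattern
        self.reference_ids = list(reference_ids) if reference_ids else None
        self.n_axes = n_axes
        self.optimal_fraction = optimal_fraction
        self.alpha = alpha

    @classmethod
    def from_fasta(cls, path, **kwargs) -> "CodonUsageAnalysis":
        return cls(read_fasta(path), **kwargs)

    # -- fitting ---------------------------------------------------------

    def _select_reference(self, retained: Sequence[CodingSequence]) -> List[str]:
        if self.reference_ids is not None:
            ids = [r.id for r in retained if r.id in set(self.reference_ids)]
            if ids:
                return ids
            raise CodonForgeError("none of the given reference_ids survived QC")
        pattern = re.compile(self.reference_pattern, re.IGNORECASE)
        ids = [r.id for r in retained if pattern.search(r.description or "")]
        if ids:
            return ids
        logger.warning(
            "no gene description matches reference pattern %r; "
            "using all genes as the CAI reference set",
            self.reference_pattern,
        )
        return [r.id for r in retained]

    def fit(self) -> "CodonUsageResults":
        retained, rejected = filter_cds(
            self.records, self.filter_config, self.code
        )
        if not retained:
            raise CodonForgeError(
                "filter stage: no CDS passed quality filtering"
            )
        tables: Dict[str, CodonCountTable] = {
            r.id: codon_counts(r, self.code).without_stops(self.code)
            for r in retained
        }
        gene_list = list(tables.values())

        # CAI weights need only counts; pick the reference first
        ref_ids = self._select_reference(retained)
        weights = cai_weights((tables[g] for g in ref_ids), self.code)

        gene_table = gene_index_table(
            [(g, t) for g, t in tables.items()], self.code, weights
        )

        pooled_usage = aggregate_usage_table(
            (codon_counts(r, self.code) for r in retained), self.code
        )

        composition_corr = self._composition_correlations(gene_table)
        regressions = self._regressions(gene_table, tables)

        rscu_matrix = build_rscu_matrix(
            gene_list, self.code, gene_ids=list(tables)
        )
        coa_result = correspondence_analysis(rscu_matrix, self.n_axes)
        orient_axes(coa_result, anchor=gene_table["gc3"])
        axis_index = axis_index_correlations(coa_result, gene_table)
        axis_codon = axis_codon_correlations(coa_result, rscu_matrix)

        optimal = detect_optimal_codons(
            gene_list,
            coa_result.gene_coords["axis1"],
            gene_table["enc"],
            self.code,
            fraction=self.optimal_fraction,
            alpha=self.alpha,
        )

        return CodonUsageResults(
            model=self,
            retained=retained,
            rejected=rejected,
            gene_tables=tables,
            cai_reference_ids=list(ref_ids),
            cai_weights=weights,
            gene_table=gene_table,
            pooled_usage=pooled_usage,
            composition_correlations=composition_corr,
            regressions=regressions,
            rscu_matrix=rscu_matrix,
            coa=coa_result,
            axis_index_correlations=axis_index,
            axis_codon_correlations=axis_codon,
            optimal_codons=optimal,
        )

    # -- analysis pieces -------------------------------------------------

    def _composition_correlations(self, gene_table: pd.DataFrame) -> pd.DataFrame:
        """Spearman (one-tailed, observed direction) between total base
        contents (rows) and silent-site contents (columns)."""
        rows = ["a", "t", "g", "c", "gc"]
        cols = ["a3", "t3", "g3", "c3", "gc3"]
        out = pd.DataFrame(
            np.nan,
            index=rows,
            columns=pd.MultiIndex.from_product([cols, ("rho", "p")]),
        )
        for rv in rows:
            for cv in cols:
                try:
                    rho, _ = spearman(gene_table[rv], gene_table[cv])
                    alt = "greater" if rho >= 0 else "less"
                    rho, p = spearman(gene_table[rv], gene_table[cv],
                                      alternative=alt)
                except UndefinedStatisticError:
                    continue
                out.loc[rv, (cv, "rho")] = rho
                out.loc[rv, (cv, "p")] = p
        return out

    def _regressions(
        self, gene_table: pd.DataFrame, tables: Dict[str, CodonCountTable]
    ) -> Dict[str, RegressionResult]:
        out: Dict[str, RegressionResult] = {}
        for gc_col in ("gc", "gc1", "gc2", "gc3"):
            try:
                out[f"scuo_vs_{gc_col}"] = scuo_gc_fit(
                    gene_table[gc_col], gene_table["scuo"]
                )
            except (UndefinedStatisticError, ValueError):
                pass
        try:
            out["neutrality"] = neutrality_fit(
                gene_table["gc3"], gene_table["gc12"]
            )
        except (UndefinedStatisticError, ValueError):
            pass
        pr2 = self.pr2_points(tables)
        if len(pr2) >= 3 and pr2["x"].nunique() > 1:
            out["pr2"] = linear_fit(pr2["x"], pr2["y"])
        return out

    def pr2_points(self, tables: Dict[str, CodonCountTable]) -> pd.DataFrame:
        rows = []
        for gene_id, table in tables.items():
            try:
                point = pr2_point(table, self.code)
            except UndefinedStatisticError:
                continue
            rows.append({"id": gene_id, "x": point.x, "y": point.y})
        frame = pd.DataFrame(rows, columns=["id", "x", "y"])
        return frame.set_index("id")


@dataclass
class CodonUsageResults:
    """Everything the fitted analysis produced."""

    model: CodonUsageAnalysis
    retained: List[CodingSequence]
    rejected: List[CodingSequence]
    gene_tables: Dict[str, CodonCountTable]
    cai_reference_ids: List[str]
    cai_weights: CAIWeights
    gene_table: pd.DataFrame
    pooled_usage: pd.DataFrame
    composition_correlations: pd.DataFrame
    regressions: Dict[str, RegressionResult]
    rscu_matrix: pd.DataFrame
    coa: COAResult
    axis_index_correlations: pd.DataFrame
    axis_codon_correlations: pd.DataFrame
    optimal_codons: pd.DataFrame

    # -- derived ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.retained)

    def enc_residuals(self) -> pd.Series:
        """Per-gene ENC minus Wright's expectation at the gene's GC3."""
        res = enc_residuals(self.gene_table["enc"], self.gene_table["gc3"])
        return pd.Series(res, index=self.gene_table.index, name="enc_residual")

    def optimal_codon_list(self, alpha: float | None = None) -> List[str]:
        table = self.optimal_codons
        if alpha is not None:
            table = table[table["p"] <= alpha]
        return sorted(table.loc[table["optimal"], "codon"])

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        g = self.gene_table
        lines = [
            "Synonymous codon usage analysis",
            "=" * 47,
            f"Genes retained / rejected : {len(self.retained)} / {len(self.rejected)}",
            f"Total sense codons        : {int(g['length_codons'].sum())}",
            f"CAI reference genes       : {len(self.cai_reference_ids)}",
            "",
            "Per-gene indices (mean +/- SD)",
            "-" * 47,
        ]
        for col, label, scale in [
            ("enc", "ENC", 1.0), ("cai", "CAI", 1.0), ("scuo", "SCUO", 1.0),
            ("gc", "GC%", 100.0), ("gc3", "GC3%", 100.0),
        ]:
            lines.append(
                f"{label:26s}: {g[col].mean() * scale:8.2f} +/- "
                f"{g[col].std() * scale:.2f}"
            )
        lines += ["", "Diagnostics", "-" * 47]
        for name, reg in self.regressions.items():
            lines.append(
                f"{name:26s}: slope={reg.slope:+.4f} "
                f"intercept={reg.intercept:.4f} r={reg.r:+.3f} p={reg.p:.3g}"
            )
        frac = ", ".join(
            f"{100 * f:.2f}%" for f in self.coa.inertia_fractions
        )
        lines += [
            "",
            f"CA axis inertia           : {frac}",
            f"Putative optimal codons   : {len(self.optimal_codon_list())} "
            f"({', '.join(self.optimal_codon_list()) or 'none'})",
        ]
        return "\n".join(lines)

    # -- artifacts -------------------------------------------------------

    def save_artifacts(self, outdir: str | Path) -> Dict[str, str]:
        """Write the full TSV artifact set plus a JSON manifest; returns
        the artifact name -> path mapping."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, str] = {}

        def save(name: str, writer) -> None:
            path = outdir / name
            writer(path)
            paths[name] = str(path)

        save("rejections.tsv",
             lambda p: write_rejection_log(self.rejected, p))
        save("gene_indices.tsv",
             lambda p: self.gene_table.to_csv(p, sep="\t"))
        save("pooled_usage.tsv",
             lambda p: self.pooled_usage.round(2).to_csv(p, sep="\t",
                                                         index=False))
        save("composition_correlations.tsv",
             lambda p: self.composition_correlations.to_csv(p, sep="\t"))

        reg_rows = [
            {"analysis": name, "slope": r.slope, "intercept": r.intercept,
             "r": r.r, "p": r.p, "n": r.n, "corr_method": r.corr_method}
            for name, r in self.regressions.items()
        ]
        save("regressions.tsv",
             lambda p: pd.DataFrame(reg_rows).to_csv(p, sep="\t", index=False))

        inertia = pd.DataFrame({
            "axis": [f"axis{k+1}" for k in range(self.coa.n_axes)],
            "inertia": self.coa.inertia,
            "percent_of_total": 100.0 * self.coa.inertia_fractions,
        })
        save("coa_inertia.tsv",
             lambda p: inertia.to_csv(p, sep="\t", index=False))
        save("coa_gene_coordinates.tsv",
             lambda p: self.coa.gene_coords.to_csv(p, sep="\t"))
        save("coa_axis_index_correlations.tsv",
             lambda p: self.axis_index_correlations.to_csv(p, sep="\t"))
        save("coa_axis_codon_correlations.tsv",
             lambda p: self.axis_codon_correlations.to_csv(p, sep="\t"))
        save("optimal_codons.tsv",
             lambda p: self.optimal_codons.to_csv(p, sep="\t", index=False))

        manifest = {
            "codonforge_version": __version__,
            "n_input": len(self.retained) + len(self.rejected),
            "n_retained": len(self.retained),
            "genetic_code": self.model.code.name,
            "config": {
                "min_length_nt": self.model.filter_config.min_length_nt,
                "dedupe": self.model.filter_config.dedupe,
                "reference_pattern": self.model.reference_pattern,
                "n_axes": self.model.n_axes,
                "optimal_fraction": self.model.optimal_fraction,
                "alpha": self.model.alpha,
            },
            "artifacts": sorted(paths),
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["config"], sort_keys=True).encode()
        ).hexdigest()[:16]
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2) + "\n")
        paths["manifest.json"] = str(path)
        return paths

    # -- plots -----------------------------------------------------------

    def plot_enc_gc3(self, ax=None):
        """ENC against GC3 with Wright's expected curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.gene_table
        ax.scatter(g["gc3"], g["enc"], s=8, alpha=0.5, label="genes")
        s = np.linspace(0.0, 1.0, 200)
        ax.plot(s, expected_enc(s), "r-", label="expected (no selection)")
        ax.set_xlabel("GC3s")
        ax.set_ylabel("ENC")
        ax.set_ylim(15, 63)
        ax.legend()
        return ax

    def plot_neutrality(self, ax=None):
        """GC12 against GC3 with the fitted neutrality line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.gene_table
        ax.scatter(g["gc3"], g["gc12"], s=8, alpha=0.5)
        reg = self.regressions.get("neutrality")
        if reg is not None:
            xs = np.linspace(g["gc3"].min(), g["gc3"].max(), 2)
            ax.plot(xs, reg.predict(xs), "r-",
                    label=f"slope={reg.slope:.3f}")
            ax.legend()
        ax.set_xlabel("GC3s")
        ax.set_ylabel("GC12")
        return ax

    def plot_pr2(self, ax=None):
        """PR2 bias plot with the (0.5, 0.5) parity origin."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pr2 = self.model.pr2_points(self.gene_tables)
        ax.scatter(pr2["x"], pr2["y"], s=8, alpha=0.5)
        ax.axhline(0.5, color="grey", lw=0.8)
        ax.axvline(0.5, color="grey", lw=0.8)
        ax.set_xlabel("G3 / (G3 + C3)  (fourfold sites)")
        ax.set_ylabel("A3 / (A3 + T3)  (fourfold sites)")
        return ax


def run_pipeline(input_path, outdir, **model_kwargs) -> CodonUsageResults:
    """Convenience wrapper: FASTA in, artifact directory out."""
    model = CodonUsageAnalysis.from_fasta(input_path, **model_kwargs)
    results = model.fit()
    results.save_artifacts(outdir)
    return results
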