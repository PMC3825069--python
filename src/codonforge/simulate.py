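"""Synthetic CDS generator with controlled mutation and selection.

The generator emulates the two forces that codon-usage diagnostics are
meant to separate:

* **Mutational pressure** — each gene draws a third-position GC
  probability *s* from a Beta distribution; within every synonymous
  family the G/C-ending codons jointly receive probability *s* and the
  A/T-ending codons 1-s, so a gene's silent-site GC is binomially
  distributed around its *s*.  First/second-position composition is
  coupled to *s* through a controllable tilt of the amino-acid profile
  (``position_coupling``), which is what gives mutation-dominated
  genomes their positive neutrality-plot trend.
* **Translational selection** — each gene draws an expression level;
  with ``selection_strength > 0`` a designated preferred codon per
  family receives an extra multiplicative weight
  ``exp(selection_strength * expression)``, concentrating usage in
  highly expressed genes the way selection on translation does.

Every generated gene starts with ATG, ends with a uniformly chosen stop
codon, contains no internal stop and is at least 300 nt long, so the
whole set passes the default CDS filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cds_io import CodingSequence
from .genetic_code import GeneticCode, default_code

#: Typical average amino-acid frequencies of a microbial proteome.
DEFAULT_AA_PROFILE: Dict[str, float] = {
    "A": 0.095, "R": 0.055, "N": 0.040, "D": 0.052, "C": 0.012,
    "Q": 0.044, "E": 0.058, "G": 0.074, "H": 0.022, "I": 0.060,
    "L": 0.105, "K": 0.044, "M": 0.028, "F": 0.039, "P": 0.043,
    "S": 0.058, "T": 0.054, "W": 0.014, "Y": 0.032, "V": 0.071,
}

#: One designated preferred codon in each of 12 synonymous families.
DEFAULT_PREFERRED_CODONS: FrozenSet[str] = frozenset({
    "TTC", "CTG", "ATC", "GTT", "TCC", "CCA",
    "ACT", "GCA", "TAC", "CAT", "CAG", "AAC",
})


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic genome.

    ``gc3_beta`` defaults to a Beta(24.5, 64.9) mutational-bias
    distribution (mean 0.274, SD 0.047 — an AT-rich organelle-like
    genome); ``length_range`` is the inclusive range of body codons
    (start and stop are added on top), uniform 120-600 so every CDS
    clears a 300-nt minimum with small-sample noise kept modest.
    """

    n_genes: int = 500
    length_range: Tuple[int, int] = (120, 600)
    aa_profile: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_PROFILE)
    )
    gc3_beta: Tuple[float, float] = (24.5, 64.9)
    position_coupling: float = 0.2
    selection_strength: float = 0.0
    preferred_codons: FrozenSet[str] = DEFAULT_PREFERRED_CODONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        if self.gc3_beta[0] <= 0 or self.gc3_beta[1] <= 0:
            raise ValueError("gc3_beta parameters must be positive")
        if not 0 <= self.position_coupling <= 1:
            raise ValueError("position_coupling must lie in [0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        total = sum(self.aa_profile.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"aa_profile sums to {total}, expected 1")


def mutation_dominated_spec(**overrides) -> SyntheticSpec:
    """Pure mutational-pressure conditions (no selection)."""
    return replace(SyntheticSpec(), selection_strength=0.0, **overrides)


def selection_dominated_spec(**overrides) -> SyntheticSpec:
    """Strong expression-linked selection on a homogeneous mutational
    background (tight Beta keeps GC3 variation from masquerading as a
    bias gradient)."""
    base = SyntheticSpec(
        selection_strength=8.0,
        gc3_beta=(200.0, 200.0),
        position_coupling=0.0,
    )
    return replace(base, **overrides)


def _family_mutation_weights(code: GeneticCode, s: float) -> Dict[str, float]:
    """Within-family codon probabilities under third-position bias ``s``:
    the G/C-ending codons of a family share probability s, the A/T-ending
    share 1-s (families with only one ending class are uniform)."""
    weights: Dict[str, float] = {}
    for family in code.families.values():
        gc_end = [c for c in family if c[2] in "GC"]
        at_end = [c for c in family if c[2] in "AT"]
        if gc_end and at_end:
            for c in gc_end:
                weights[c] = s / len(gc_end)
            for c in at_end:
                weights[c] = (1.0 - s) / len(at_end)
        else:
            for c in family:
                weights[c] = 1.0 / len(family)
    return weights


def _aa_gc12(code: GeneticCode) -> Dict[str, float]:
    """Mean GC fraction of the first two codon positions per amino acid."""
    out = {}
    for aa, family in code.families.items():
        vals = [sum(b in "GC" for b in c[:2]) / 2.0 for c in family]
        out[aa] = float(np.mean(vals))
    return out


def _tilt_profile(
    probs: np.ndarray, g: np.ndarray, target: float
) -> np.ndarray:
    """Exponentially tilt ``probs`` so the expectation of ``g`` hits
    ``target`` (clamped to the achievable open interval)."""
    lo, hi = g.min(), g.max()
    target = min(max(target, lo + 1e-4), hi - 1e-4)

    def gap(eta: float) -> float:
        w = probs * np.exp(eta * g)
        return float(w @ g / w.sum()) - target

    if abs(gap(0.0)) < 1e-12:
        return probs
    eta = brentq(gap, -60.0, 60.0)
    w = probs * np.exp(eta * g)
    return w / w.sum()


def generate_genome(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> Tuple[List[CodingSequence], pd.DataFrame]:
    """Generate a genome under ``spec``; deterministic for a fixed seed.

    Returns the CDS records and a truth table (indexed by gene id) with
    each gene's mutational bias ``s``, expression level, body length in
    codons, and realised GC3 target; the preferred-codon set and seed are
    stored in ``truth.attrs``.
    """
    code = code or default_code()
    rng = np.random.default_rng(spec.seed)
    aa_order = sorted(spec.aa_profile)
    base_probs = np.array([spec.aa_profile[a] for a in aa_order])
    base_probs = base_probs / base_probs.sum()
    g = np.array([_aa_gc12(code)[a] for a in aa_order])
    mu0 = float(base_probs @ g)
    s_mean = spec.gc3_beta[0] / sum(spec.gc3_beta)

    codons = list(code.sense_codons)
    codon_aa = [code.codon_to_aa[c] for c in codons]
    aa_pos = {a: i for i, a in enumerate(aa_order)}
    stops = sorted(code.stop_codons)

    records: List[CodingSequence] = []
    rows = []
    n_digits = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        s = float(rng.beta(*spec.gc3_beta))
        expr = float(rng.random())
        length = int(rng.integers(spec.length_range[0],
                                  spec.length_range[1] + 1))
        target = mu0 + spec.position_coupling * (s - s_mean)
        aa_probs = _tilt_profile(base_probs, g, target)

        mut = _family_mutation_weights(code, s)
        weights = np.empty(len(codons))
        for j, codon in enumerate(codons):
            w = mut[codon]
            if spec.selection_strength > 0 and codon in spec.preferred_codons:
                w *= np.exp(spec.selection_strength * expr)
            weights[j] = w * aa_probs[aa_pos[codon_aa[j]]]
        # renormalise family weights so amino-acid frequencies stay fixed
        fam_tot = np.zeros(len(aa_order))
        for j, codon in enumerate(codons):
            fam_tot[aa_pos[codon_aa[j]]] += weights[j]
        for j, codon in enumerate(codons):
            weights[j] *= aa_probs[aa_pos[codon_aa[j]]] / fam_tot[aa_pos[codon_aa[j]]]
        probs = weights / weights.sum()

        body = rng.choice(len(codons), size=length, p=probs)
        stop = stops[int(rng.integers(len(stops)))]
        seq = "ATG" + "".join(codons[k] for k in body) + stop
        gene_id = f"synth{i + 1:0{n_digits}d}"
        desc = (f"{gene_id} synthetic CDS seed={spec.seed} s={s:.4f} "
                f"expression={expr:.4f}")
        records.append(CodingSequence(id=gene_id, seq=seq, description=desc))
        rows.append({"id": gene_id, "s": s, "expression": expr,
                     "length_codons": length, "gc12_target": target})

    truth = pd.DataFrame(rows).set_index("id")
    truth.attrs["seed"] = spec.seed
    truth.attrs["preferred_codons"] = sorted(spec.preferred_codons)
    truth.attrs["selection_strength"] = spec.selection_strength
    return records, truth


def make_reference_set(truth: pd.DataFrame, fraction: float = 0.1) -> List[str]:
    """Ids of the top-``fraction`` genes by expression (at least one),
    for use as the highly-expressed CAI reference set."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = max(1, int(np.floor(fraction * len(truth))))
    ordered = truth.sort_values("expression", ascending=False, kind="mergesort")
    return list(ordered.index[:k])


def write_truth_table(truth: pd.DataFrame, path) -> None:
    """TSV truth table (id, s, expression, length_codons, gc12_target)."""
    truth.to_csv(path, sep="\t")
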