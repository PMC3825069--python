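"""Mutation-vs-selection diagnostics and rank-correlation machinery.

* Wright's expected ENC-GC3 curve and per-gene residuals from it.
* Neutrality plot (GC12 against GC3) regression.
* Parity-rule-2 (PR2) bias coordinates at fourfold-degenerate sites.
* SCUO against GC fits.
* Spearman rank correlation with one-tailed options and exact permutation
  p-values at small n.

Genes shaped only by third-position mutational bias are expected to lie
on the Wright curve and to show a positive GC12-GC3 trend; translational
selection pulls genes below the curve and flattens the neutrality slope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence, Tuple

import numpy as np
from scipy import stats

from .counts import CodonCountTable
from .exceptions import UndefinedStatisticError
from .genetic_code import GeneticCode


def expected_enc(s):
    """Wright's expected ENC under random usage at third-position GC ``s``:
    ``2 + s + 29 / (s^2 + (1-s)^2)``.  Accepts scalars or arrays."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("GC3 fraction must lie in [0, 1]")
    value = 2.0 + s + 29.0 / (s ** 2 + (1.0 - s) ** 2)
    return float(value) if value.ndim == 0 else value


@dataclass(frozen=True)
class RegressionResult:
    """Least-squares line plus a correlation coefficient and its p-value."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int
    corr_method: str = "spearman"

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 10,
) -> Tuple[float, float]:
    """Spearman rho on midranks with a configurable alternative.

    ``alternative`` is one of ``"two-sided"``, ``"greater"`` (positive
    association) or ``"less"``.  For n <= ``exact_max_n`` the p-value is
    an exact permutation probability; above that, the t-approximation
    with n - 2 degrees of freedom is used.  Ties receive mean ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedStatisticError("constant vector: rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho, alternative)
    else:
        p = _t_approx_p(rho, n, alternative)
    return rho, p


def _t_approx_p(rho: float, n: int, alternative: str) -> float:
    r = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    if alternative == "two-sided":
        return 2.0 * stats.t.sf(abs(t), n - 2)
    if alternative == "greater":
        return stats.t.sf(t, n - 2)
    if alternative == "less":
        return stats.t.cdf(t, n - 2)
    raise ValueError(f"unknown alternative {alternative!r}")


def _exact_spearman_p(rx, ry, rho, alternative, chunk: int = 120_000) -> float:
    """Exact permutation p by enumerating all orderings of one rank vector."""
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt((cx ** 2).sum() * (cy ** 2).sum())
    hits = 0
    total = 0
    tol = 1e-12
    perm_iter = itertools.permutations(range(n))
    while True:
        block = np.array(list(itertools.islice(perm_iter, chunk)), dtype=np.intp)
        if block.size == 0:
            break
        rhos = (cy[block] @ cx) / denom
        if alternative == "two-sided":
            hits += int(np.count_nonzero(np.abs(rhos) >= abs(rho) - tol))
        elif alternative == "greater":
            hits += int(np.count_nonzero(rhos >= rho - tol))
        elif alternative == "less":
            hits += int(np.count_nonzero(rhos <= rho + tol))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        total += block.shape[0]
    return hits / total


def linear_fit(
    x: Sequence[float],
    y: Sequence[float],
    corr_method: str = "spearman",
    alternative: str = "observed-one-tailed",
) -> RegressionResult:
    """Ordinary least-squares line y = slope*x + intercept, with a
    correlation coefficient attached.

    ``corr_method`` chooses the reported r ("spearman" or "pearson");
    ``alternative="observed-one-tailed"`` reports the one-tailed p in the
    direction of the observed correlation, matching the blanket one-tailed
    reporting convention of codon-usage tables; "two-sided", "greater" and
    "less" are also accepted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors, n >= 3")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("constant predictor: slope undefined")
    slope, intercept = np.polyfit(x, y, 1)

    if corr_method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
        if alternative == "observed-one-tailed":
            alt = "greater" if r >= 0 else "less"
        else:
            alt = alternative
        res = stats.pearsonr(x, y, alternative=alt)
        p = float(res.pvalue)
    elif corr_method == "spearman":
        if alternative == "observed-one-tailed":
            r0 = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
            alt = "greater" if r0 >= 0 else "less"
        else:
            alt = alternative
        r, p = spearman(x, y, alternative=alt)
    else:
        raise ValueError(f"unknown corr_method {corr_method!r}")
    return RegressionResult(float(slope), float(intercept), r, p, x.size, corr_method)


def neutrality_fit(
    gc3: Sequence[float], gc12: Sequence[float], corr_method: str = "spearman",
) -> RegressionResult:
    """Neutrality-plot regression gc12 = slope*gc3 + intercept.

    A slope near 1 indicates composition at all three positions drifting
    together (pure mutational pressure); a slope near 0 indicates first
    and second positions decoupled from third-position pressure
    (selection dominating)."""
    return linear_fit(gc3, gc12, corr_method=corr_method)


def scuo_gc_fit(
    gc_k: Sequence[float], scuo_values: Sequence[float],
    corr_method: str = "spearman",
) -> RegressionResult:
    """Linear fit of SCUO against a GC component (GC, GC1, GC2 or GC3)."""
    return linear_fit(gc_k, scuo_values, corr_method=corr_method)


class PR2Point(NamedTuple):
    """Parity-rule-2 coordinates at fourfold-degenerate third positions:
    x = G3/(G3+C3), y = A3/(A3+T3).  (0.5, 0.5) is the no-bias origin."""

    x: float
    y: float


def pr2_point(
    counts: CodonCountTable, code: GeneticCode, orientation: str = "sueoka"
) -> PR2Point:
    """PR2 bias coordinates restricted to the code's fourfold boxes.

    ``orientation="sueoka"`` puts G/(G+C) on x and A/(A+T) on y;
    ``"swapped"`` exchanges the axes.
    """
    tally = dict.fromkeys("ACGT", 0)
    for prefix in code.fourfold_boxes:
        for base in "ACGT":
            tally[base] += counts[prefix + base]
    at = tally["A"] + tally["T"]
    gc = tally["G"] + tally["C"]
    if at == 0 or gc == 0:
        raise UndefinedStatisticError(
            "PR2 undefined: zero A+T or G+C at fourfold third positions"
        )
    x = tally["G"] / gc
    y = tally["A"] / at
    if orientation == "swapped":
        x, y = y, x
    elif orientation != "sueoka":
        raise ValueError(f"unknown orientation {orientation!r}")
    return PR2Point(x, y)


def enc_residuals(enc_values, gc3_values):
    """Observed ENC minus Wright's expectation at each gene's GC3."""
    enc_values = np.asarray(enc_values, dtype=float)
    return enc_values - expected_enc(gc3_values)
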