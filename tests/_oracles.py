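"""Independent brute-force oracles, coded directly from the published
definitions with explicit loops.  Kept deliberately separate from (and
structurally unlike) the package implementations they check."""

import itertools
import math

import numpy as np


def wright_enc_oracle(counts: dict, families: dict) -> float:
    """Wright's effective number of codons straight from the definitions:
    per-family homozygosity F = (n*sum(p^2)-1)/(n-1), averaged per
    degeneracy class, Nc = N1 + sum_k m_k / Fbar_k for the standard-code
    class structure.  ``families`` maps amino acid -> codon list."""
    class_f = {}
    class_m = {}
    n_single = 0
    for aa, codons in families.items():
        k = len(codons)
        if k == 1:
            n_single += 1
            continue
        class_m[k] = class_m.get(k, 0) + 1
        n = sum(counts.get(c, 0) for c in codons)
        if n <= 1:
            continue
        total = 0.0
        for c in codons:
            p = counts.get(c, 0) / n
            total += p * p
        f = (n * total - 1.0) / (n - 1.0)
        if f > 0:
            class_f.setdefault(k, []).append(f)
    means = {k: sum(v) / len(v) for k, v in class_f.items()}
    nc = float(n_single)
    for k in sorted(class_m):
        if k in means:
            fbar = means[k]
        elif k == 3 and 2 in means and 4 in means:
            fbar = (means[2] + means[4]) / 2.0
        else:
            fbar = sum(means.values()) / len(means)
        nc += class_m[k] / fbar
    return min(nc, 61.0)


def midrank_spearman_oracle(x, y) -> float:
    """Spearman rho as Pearson correlation of hand-computed midranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


def brute_force_ca(matrix: np.ndarray):
    """Correspondence analysis via explicit construction of the
    standardized residual matrix and an eigendecomposition of S S^T
    (a different route than the implementation's direct SVD).

    Returns (inertias descending, row principal coordinates up to sign,
    total inertia)."""
    m = np.asarray(matrix, dtype=float)
    grand = m.sum()
    p = m / grand
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = np.empty_like(p)
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            e = r[i] * c[j]
            s[i, j] = (p[i, j] - e) / math.sqrt(e)
    w, v = np.linalg.eigh(s @ s.T)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    k = min(m.shape) - 1
    coords = v[:, :k] * np.sqrt(w[:k]) / np.sqrt(r)[:, None]
    return w[:k], coords, float(w[:k].sum())


def exact_spearman_null_p(x, y, observed, alternative="two-sided"):
    """Exact permutation p-value for Spearman rho by full enumeration
    (small n only)."""
    rho_obs = observed
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = midrank_spearman_oracle(x, [y[i] for i in perm])
        if alternative == "two-sided":
            hit = abs(rho) >= abs(rho_obs) - 1e-12
        elif alternative == "greater":
            hit = rho >= rho_obs - 1e-12
        else:
            hit = rho <= rho_obs + 1e-12
        count += hit
        total += 1
    return count / total
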