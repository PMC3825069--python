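# Methods

This note records the definitions, conventions and design choices behind
codonforge, in the spirit of a model-description document: what is
computed, under which assumptions, and what the synthetic-data tests do
and do not demonstrate.

## CDS quality model

A coding sequence enters the analysis only if it

1. is longer than 300 nucleotides (i.e. ≥ 301 nt, measured on the full
   CDS including its stop codon) — short CDS make per-gene codon
   frequencies too noisy for the indices below;
2. has a length divisible by 3;
3. begins with an initiator codon — default {ATG, GTG, TTG}, the
   conventional bacterial set under NCBI translation table 11 (the full
   table-11 initiator set or strict ATG can be configured);
4. ends with a stop codon and contains no internal stop;
5. contains no ambiguity codes (such records are rejected outright
   rather than partially counted);
6. is not an exact full-sequence duplicate of an earlier retained record
   (first occurrence kept; deduplication can be switched off).

Failures are classifications: the retained and rejected lists always
partition the input, each rejected record carrying reason codes, and
filtering is idempotent on the retained set.

## Composition conventions

All base-content quantities are computed over sense codons; stop codons
never enter composition or indices (they are still counted and appear as
TER rows in pooled usage tables). "GC3" throughout means the
silent-site variant **GC3s**: G+C at third positions of codons whose
amino acid has at least two synonymous codons, excluding Met, Trp and
stops — the convention of the classic codon-usage tools.  The plain
third-position GC over all sense codons is exposed alongside
(`gc3_all`) for comparison.  GC12 is the arithmetic mean of GC1 and GC2.

## Indices

**RSCU.** `RSCU_ij = k_i x_ij / n_i`.  An unobserved family yields NaN
(undefined), never 0; only when building the correspondence-analysis
matrix are such entries imputed as 0 (logged per gene), which keeps rows
comparable without inventing usage.

**ENC.** Wright's estimator with family homozygosity
`F̂ = (nΣp̂² − 1)/(n − 1)` averaged within degeneracy classes and
`N_c = N₁ + Σ_k m_k / F̄_k` (for the standard code: 2 + 9/F̄₂ + 1/F̄₃ +
5/F̄₄ + 3/F̄₆, with Leu/Ser/Arg treated as single six-fold families).
Families with n ≤ 1, or with F̂ = 0 (possible at very small n and
incompatible with the harmonic combination), are skipped.  A missing
three-fold class average is imputed as (F̄₂ + F̄₄)/2, the standard
fallback for unobserved Ile; if any other class has no estimable family
its average is imputed as the mean of the defined class averages, and
ENC is undefined only when no family at all is estimable.  Estimates
above 61 (very even usage at small n) are clamped to 61; the raw value
is available via `clamp=False` and logged at debug level.

**CAI.** Weights are relative adaptiveness within each family of the
*pooled* reference counts; zero-count reference codons receive a floor
weight of 0.01 (configurable) rather than 0, so genes using them keep a
finite CAI.  The gene score is a geometric mean over codon occurrences,
computed in log space to avoid underflow on long genes; Met, Trp and
stops are excluded.  The reference set is chosen by a configurable
regex on FASTA descriptions (default "ribosomal protein", the
conventional highly-expressed proxy) or by explicit gene ids; if the
pattern matches nothing, all genes are used and a warning is emitted.

**SCUO.** The information-theoretic definition with natural logarithms:
per observed family `O_i = (ln k_i − H_i)/ln k_i`, combined with
weights `F_i` equal to each family's share of codons among all codons
of degeneracy ≥ 2.  0 for perfectly uniform usage, 1 when each family
uses a single codon.

**GRAVY / aromaticity.** Mean Kyte–Doolittle hydropathy of the
translated residue counts (values from biopython's published table) and
the Phe+Tyr+Trp residue fraction.

## Diagnostics

The expected-ENC curve is Wright's approximation
`N_c(s) = 2 + s + 29/(s² + (1−s)²)`; per-gene residuals are observed
ENC minus this expectation at the gene's GC3s.  Neutrality and SCUO~GC
fits are ordinary least squares with an attached correlation
coefficient.  Spearman is the default correlation everywhere (the
field's blanket convention for these tables) and Pearson is available
as a switch, since published regression-context r values are sometimes
Pearson; reported p-values are one-tailed in the direction of the
observed coefficient unless a two-sided alternative is requested.
Spearman p-values use an exact permutation enumeration for n ≤ 10 and
the t-approximation with n − 2 degrees of freedom above; ties receive
mean ranks.  No multiple-testing correction is applied to the
correlation tables, matching standard practice for these descriptive
screens.

PR2 coordinates use Sueoka's orientation — x = G3/(G3+C3),
y = A3/(A3+T3) — restricted to the eight fourfold-degenerate boxes
(GCN, CGN, GGN, CTN, CCN, TCN, ACN, GTN under table 11, derived from
the code rather than hard-coded); a swapped orientation is available
because published PR2 plots are not always labelled.

## Correspondence analysis

Input is the gene × 59 RSCU matrix (not raw counts), with undefined
entries imputed as 0.  Standard CA: P = M/grand total, standardized
residuals S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD of S, axis inertia
σ_k², principal coordinates for rows and columns.  All-zero columns
(codons never observed) are dropped from the decomposition and reported
with NaN coordinates.  Five axes are retained by default.  Axis signs
are arbitrary, so each axis is oriented to correlate non-negatively
with per-gene GC3s (tie-break: positive first-codon loading), making
outputs reproducible run to run.  Total inertia equals the matrix
chi-square statistic divided by its grand total; the implementation is
cross-checked in the tests against a loop-based eigendecomposition
oracle and against R `vegan::cca`.

## Optimal codons

The 5 % of genes at each extreme of CA axis 1 (set sizes
floor(0.05·N), per side) are pooled — pooling, rather than averaging
per-gene frequencies, because the chi-square requires integer counts.
For each of the 59 sense codons with synonymous alternatives a 2×2
table [codon count, synonymous-alternative count] × [high-bias pool,
low-bias pool] is tested with Pearson's chi-square, df = 1, without
continuity correction (a Yates-corrected variant is available).
Because the axis sign is arbitrary, the high-bias pool is anchored as
the extreme with the lower mean ENC.  A codon is flagged optimal when
p ≤ α (default 0.05, with the stricter 0.001 cut available — both
conventions appear in the literature) *and* its RSCU is higher in the
high-bias pool.  Families absent from either pool are reported
undefined and never flagged.

## Synthetic genome model

Each gene draws: a body length uniform on 120–600 codons (so every CDS
clears the 300-nt filter with small-sample noise kept modest), a
mutational bias s ~ Beta(24.5, 64.9) by default (mean 0.274,
SD ≈ 0.047 — an AT-rich organelle-like silent-site GC distribution),
and an expression level uniform on [0, 1].  Codons are drawn i.i.d.:
amino acids from a typical microbial frequency profile, then a synonym
with the family's G/C-ending codons jointly carrying probability s and
the A/T-ending codons 1 − s, so a gene's silent-site GC is exactly
binomial around its s.  First/second-position composition is coupled to
s by exponentially tilting the amino-acid profile until its expected
GC12 equals `μ₀ + coupling·(s − E[s])`; the neutrality slope therefore
rises monotonically with the coupling parameter and sits near it
(attenuated slightly by the sampling noise in per-gene GC3).  With
selection on, one designated preferred codon in each of 12 families
gains weight `exp(strength · expression)`; the selection-dominated
scenario uses strength 8 on a tight Beta(200, 200) mutational
background so the bias gradient along CA axis 1 is driven by selection
rather than GC3 variation.  ATG is prepended and a uniformly chosen
stop appended; internal stops are impossible by construction.  A single
seeded generator drives all draws (seed recorded in FASTA headers and
in the truth table), so identical seeds give byte-identical output.

What the generator does *not* emulate: amino-acid composition differences
between genes, length/expression correlations, strand- or
replication-associated asymmetries (PR2 deviations), dinucleotide or
codon-pair effects, and phylogenetic correlation among genes.  Passing
recovery tests therefore show that the statistics detect the planted
mutational and selective structure under an i.i.d. codon model — not
that real genomes satisfy these assumptions.

## Problem sizes and numerical choices

The test suite exercises genomes of 400 genes (mutation-dominated,
seed 5) and 500 genes (selection-dominated, seed 11), sizes at which
the diagnostic contrasts are unambiguous while the whole suite stays
fast.  Chi-square recovery of the 12 planted preferred codons is
checked at α = 0.01 (sensitivity ≥ 0.9, ≤ 2 false positives).  The
desk-scale reference values recomputed by `scripts/acceptance.py` are
exact two-decimal RSCU calculations on published pooled count tables
and involve no randomness; the `--seed` option exists for forward
compatibility and seeds nothing today.  Numerical tolerances: CA is
validated to 1e-8 against the brute-force oracle; fraction invariants
to 1e-9; ENC comparisons at pytest's default relative tolerance.

## Known limitations

- ENC treats Leu/Ser/Arg as single six-fold families (Wright's original
  scheme); tools that split them into sub-families give slightly
  different values for GC-extreme genes.
- CAI depends on the reference-set choice; with no description match
  the all-genes fallback weakens its interpretation as a translational
  proxy.
- The published-table reproduction is desk-scale (pooled RSCU); exact
  genome-scale reproduction depends on annotation vintage,
  deduplication convention and the GC3 convention of the original
  tools, and is checked with documented tolerances only when the
  genome FASTA files are supplied locally.
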