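# Methods

## Scope and data model

The package analyses synonymous codon usage in a set of coding sequences.
The atomic unit is a `CdsRecord` (one gene, uppercased, U→T normalized);
counting produces a `CodonCountTable` over all 64 codons, and every index
is defined on top of the standard genetic code's synonymous-family
structure (nine 2-fold amino acids, Ile as the lone 3-fold, five 4-fold,
three 6-fold; Met and Trp single-codon; stops TAA/TAG/TGA).

## QC filtering

A record is retained iff it starts with ATG, ends with a stop codon, is
strictly longer than `min_len_nt` (default 300 nt — with triplet structure
the effective minimum is 303 nt), has length divisible by three, and is
the first occurrence of its exact nucleotide string. Each rejected record
is attributed to the *first* failing rule in that order, so tallies always
sum to the input count and filtering is idempotent. Two deliberate
conventions: internal stop codons do **not** reject a gene (they are
logged and excluded from translation-based indices), and codons containing
ambiguity codes are skipped from counting rather than rejecting the gene.

## Composition

The terminal stop codon is excluded from all per-gene indices. GC1/GC2/GC3
are G+C fractions at the three codon positions over the same codon set, so
`GC = (GC1+GC2+GC3)/3` holds exactly; `GC12 = (GC1+GC2)/2`. GC3s and the
base-specific A3s/T3s/C3s/G3s all use one denominator — third positions of
synonymous codons (families of size ≥ 2; Met, Trp and stops excluded) — so
the four base fractions sum to 1. This is slightly more self-consistent
than historical CodonW, which varies per-base denominators. Pooled
summaries report the unweighted across-gene mean ± sample SD (ddof = 1;
a single gene reports SD 0).

## RSCU

`RSCU_i = k·x_i/X_a` for codon *i* in a family of size *k* with total
`X_a`. Families with zero observations give NaN (flagged), so observed
family sums always equal family sizes. Both pooled-count RSCU and the mean
of per-gene RSCU are available (`rscu` on pooled counts vs
`mean_rscu_over_genes`): the two genuinely differ when usage covaries with
gene length or bias, and published genome tables do not always say which
was used. The stop "family" is only included on request.

## ENC

Wright's estimator with the corrected homozygosity
`F̂ = (n·Σp̂² − 1)/(n − 1)` per amino acid (undefined for n ≤ 1), averaged
within degeneracy classes and combined as
`ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`. Conventions:

- missing 3-fold or 6-fold class average → harmonic-mean fallback
  `2/(1/F̄₂ + 1/F̄₄)`;
- empty 2-fold or 4-fold class, or any zero class average → ENC undefined
  (NaN), never a fabricated value;
- finite-sample estimates above 61 are capped at 61; values below 20 are
  impossible by construction (F̂ ∈ [0, 1]).

The implementation is pinned to an independently coded oracle on random
genes to 1e-9.

## Expected ENC and the ENC ratio

`ENC_exp(s) = 2 + s + 29/(s² + (1−s)²)` with `s = GC3s`. (A common
typographic corruption of this formula, `s² + (1 − s²)`, collapses to a
constant 1 and cannot be the intended null curve; the Wright denominator
is used.) The per-gene ENC ratio is `(ENC_exp − ENC_obs)/ENC_exp`:
positive below the curve, negative above (allowed and reported). The ratio
histogram uses left-closed right-open bins of width 0.1 aligned to
multiples of the width. Note the curve's true maximum sits at s ≈ 0.5022
(60.501), a hair right of 0.5, because of the linear `+s` term.

## Neutrality regression

Ordinary least squares of GC12 on GC3 across genes (scipy `linregress`),
with Pearson r and its two-sided t-test p-value. The slope is reported as
`mutation_share` and `1 − slope` as `selection_share` because that is the
conventional reading of the neutrality plot; the package reports the
numbers without endorsing the strictly causal interpretation. Requires
≥ 3 complete points and non-degenerate GC3 variance.

## Correspondence analysis

Input is the per-gene RSCU matrix over the 59 synonymous codons — the
variant that removes amino-acid-composition effects before ordination.
Families absent from a gene are imputed at the neutral RSCU of 1.0 (and
flagged) so short genes are kept; the alternative of dropping such genes
would bias the gene set toward long genes. Classical CA follows: row and
column masses from the grand total, SVD of the standardized residuals
`(P − rcᵀ)/√(rcᵀ)`, principal coordinates for both genes and codons, and
inertia shares `σᵢ²/Σσ²`. Rank is at most `min(genes − 1, 58)`; axis signs
are fixed by making the codon with the largest absolute loading positive,
so results are deterministic. All-zero codon columns are dropped. Total
inertia equals the table's chi-square statistic divided by its grand
total, which the tests assert directly.

Correlations between axes and indices use Spearman rank by default
(robust to the heavy-tailed index distributions common in codon data),
Pearson by flag; pairs with missing values are dropped pairwise, constant
columns yield flagged NaN, and rendered tables star p < 0.05 / p < 0.01.

## CAI

Sharp–Li relative adaptiveness: `w_i = x_i / max(x_family)` from a pooled
reference set, zero-count codons floored at 0.01, families absent from
the reference set to the uninformative weight 1. CAI is the
count-weighted geometric mean of `w` over a gene's synonymous codons
(Met, Trp, stops excluded); it is 1 exactly when the gene uses only
family-maximal codons. The pipeline's default reference is the pooled
high-bias 5% subset of the ENC-ratio ordering, making the index
self-contained; a user weight table (e.g., a yeast reference) can be
supplied instead.

## Optimal codons

Genes are ordered by ENC ratio (ties broken by gene id); each extreme
subset has `ceil(fraction·N)` genes — ceiling, because 5% of 4870 genes
must give the published 244 — and the subsets must be disjoint. Subset
RSCU is pooled (counts summed first), matching published subset tables
that print per-codon subset totals. A synonymous sense codon is optimal
iff `ΔRSCU > 0.08` strictly; stops, Met and Trp are never optimal (the
published subset table leaves a stop codon with Δ = 0.18 unstarred,
confirming that exclusion). Raising the threshold can only shrink the
optimal set.

## Synthetic data generator

Each gene draws: length from a log-normal (median 420 codons, log-SD 0.6,
clipped to [101, 3000] — 101 coding codons is the shortest gene that
passes the >300 nt filter), a GC3 target uniform on [0.20, 0.95], and a
selection strength *s*, by default exponential with mean 0.7 (most genes
near-neutral, a tail strongly selected). Amino acids follow average
proteome frequencies. Within each family the codon probability is the
third-position mutation kernel (`P(G)=P(C)=gc3/2`, `P(A)=P(T)=(1−gc3)/2`,
renormalized over the family's third bases) with the preferred codon's
probability multiplied by `exp(s)`. Defaults (4870 genes, ~56% overall GC
under mid-range GC3 targets, ENC spanning roughly 20–61) emulate a
GC-rich fungal genome; the planted preferred set defaults to one C-ending
(else G-ending) codon per family. A `selection_strength`/
`selected_fraction` pair plants a "highly expressed" sub-population with
fixed *s* for parameter-recovery experiments. One `numpy` generator seeded
once drives every draw, so output FASTA is byte-identical across runs.

What the generator does **not** emulate: amino-acid composition that
covaries with expression, codon autocorrelation along genes,
length–bias correlations, isochore structure, or any phylogenetic
signal. Passing recovery tests therefore demonstrates that the pipeline's
inference machinery is correct under its own model, not that real genomes
satisfy that model.

The neutrality-set generator controls positions 1–2 and position 3
independently (`GG`/`AA` × `G`/`A` codons, deterministic rounded counts),
so a planted linear GC12–GC3 relation is realized up to rounding; with
slope 1 and zero noise the fitted slope is exactly 1.

## Problem sizes and numerical conventions

Tests run at desk scale: oracle comparisons on 200 random genes, property
suites on 1000 random count tables, neutrality recovery at n = 500–1000,
end-to-end planted-selection recovery on 1000 genes (10% selected at
s = 5, 5% subsets), where recovery of the planted 18-codon set is exact.
The full suite completes in well under a minute. Undefined values
propagate as NaN rather than raising, except where an operation's
precondition is violated outright (empty inputs, zero GC3 variance,
overlapping subsets). Floats are written to TSV with 6 decimals;
publication-style rendered tables round to 2.

## Known limitations

- Published genome-level numbers for *E. festucae* (index means, the
  0.0486 neutrality slope, 4870 retained CDS) require the original
  genome download and are not reproducible from this repository alone;
  the packaged published tables cover per-codon totals and subset RSCU.
  Those two published tables are themselves not mutually consistent in
  places (their totals differ by ~0.5%, and the printed RSCU column does
  not exactly follow from the printed counts under the pooled formula);
  the package preserves the printed values verbatim and computes honestly
  from counts.
- Only the standard genetic code is supported; no alternative start
  codons or translation tables.
- Within-group CA and frequency-based CA variants are out of scope; only
  RSCU-based CA is implemented.
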