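# Methods

## Model and procedure

The pipeline treats a differential-expression (DE) table as its primary
input and never recomputes the DE test itself: each gene carries a log2
fold-change, a multiplicity-adjusted p-value and optional per-group mean
expression (FPKM). The *expressed universe* is the set of genes with a
DE test result (`tested = true`); genes whose adjusted p is missing are
kept in the table but excluded from the universe, mirroring the NA
output of independent filtering in DE tools. A gene is *upregulated* at
level α when `padj < α` and `log2FC > 0` (direction is a parameter;
"up" is the default because the analysis targets transcriptional
activators of an upregulated programme).

Candidate TFs are the upregulated genes that are both annotated as
DNA-binding transcription factors (a GO:0003700-style gene set supplied
as input) and present in the regulon catalogue, so their target sets can
be tested. Factors of prior biological interest (e.g. TP53, RELA as the
testable NF-κB subunit) can be forced into the candidate list; forced
symbols missing from the catalogue are reported, never silently dropped.

Enrichment of a regulon among the upregulated genes is the exact
hypergeometric upper tail over the expressed universe. Both tail
conventions are implemented: `GE` = P(X ≥ k), the standard
over-representation definition and the default, and the strict `GT` =
P(X > k), retained because published tables do not always state their
convention and the calibration step (below) can score both. A TF is
called enriched at p < 0.05, with no multiplicity correction across the
handful of candidate TFs; the pathway stage, which tests hundreds of
sets, applies Benjamini–Hochberg instead. This asymmetry is deliberate
and mirrors how such analyses are reported.

## Universe calibration

Published enrichment tables print, per TF, the expressed-target count K,
the upregulated-target count k and the p-value, but usually not the
universe size N. `calibrate_universe` inverts one anchor row: it scans
integer N over a plausible transcriptome range (default 8,000–40,000)
and keeps every N whose recomputed tail probability rounds to the
anchor's printed p at its printed precision (significant digits for
scientific notation, decimal places otherwise). The chosen N is the
midpoint of the widest consistent run under the best-fitting convention
(ties favour GE). An empty scan returns an explicit no-solution result;
a k = 0 anchor is flagged uninformative.

For the human anchor row (K=6020, k=136, n=269, p = 2.10E-07) this pins
N to {16997, 16998} under GE, and the IRF8, IKZF1, TP53 and RELA rows
then reproduce at printed precision — these are asserted in the test
suite. The printed GBX2 p-value (0.56) is consistent with the strict GT
tail but not with GE at any universe that fits the other rows, so that
row is excluded from the reproduction checks. On the zebrafish side the
anchor (K=6170, k=737, n=1820, p = 4.31E-23) admits a single universe
(N = 20,475) that also reproduces the irf8 and ikzf1 rows; the gbx2,
tp53 and rela rows are not jointly consistent with any single scanned
universe under either convention and are likewise excluded — a
limitation of reconstructing an analysis whose universe and rounding
pipeline are unpublished, not of the tail computation itself (which is
verified against exhaustive enumeration).

## Numerical choices

- The tail sum is evaluated as log-gamma terms combined with
  log-sum-exp, never as `1 − CDF`; printed values near 1e-23 retain
  more than three significant digits (checked against `scipy`'s
  survival function and against exhaustive enumeration of all C(N, n)
  draws for N ≤ 12).
- A sum spanning the whole support returns exactly 1.0; the empty
  strict-tail sum at k = min(K, n) returns exactly 0.0 — the only case
  a zero probability is produced.
- BH adjustment is the standard step-up with a cap at 1, validated
  against `statsmodels`. It is monotone but not idempotent; re-applying
  it to adjusted values is a user error the tests deliberately do not
  endorse.
- Gene symbols match case-insensitively (human convention UPPER,
  zebrafish lower) and are preserved as written on output.

## Ortholog transfer

Regulons cross species through a two-column symbol map (a BioMart-style
export). One-to-many homologs are all retained (union); many-to-one
collapses by set semantics; targets without a homolog are dropped and
counted in a per-TF transfer report. The TF's own identity crosses
through the same map (SPI1 → spi1b is data, not code). Whether the
original analyses kept one-to-many expansions is generally unstated;
union is the declared default because it is what an unfiltered BioMart
export yields.

## Correlation stage

Spearman's ρ is the Pearson correlation of midranks. For n ≤ 10
tie-free samples the two-sided p-value is exact: the full n! permutation
null of ρ is enumerated once per n and cached (the statistic depends
only on the sum of squared rank differences). With ties, or for n > 10,
the t-approximation t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom is
used, with a warning when ties forced the fallback; 10! enumeration
takes seconds, 12! does not. Target confirmation uses a one-sided
threshold on ρ (default ρ > 0.70) with a two-sided p < 0.05, matching
how such filters are reported.

For the reported control-age correlation configuration (ρ = 0.69 at
n = 10, i.e. rank-difference sum S = 51), full enumeration gives a
two-sided p of 0.0306; the t-approximation gives 0.027. The value
printed alongside that ρ in the motivating study is 0.033, which neither
mode reproduces exactly — the original software's definition is not
documented, so the test asserts the enumeration value and proximity
(|Δ| < 0.005) to the reported one.

## Synthetic data

`generate_dataset` plants known structure at study scale. Defaults
emulate a case-control bulk RNA-seq design: a 17,000-gene expressed
universe, 269 upregulated genes, 12 case and 10 control samples, one
planted TF with a 600-gene regulon at enrichment odds θ = 6. Regulon
membership multiplies a gene's odds of entering the upregulated set by θ
(weighted sampling without replacement via Gumbel top-k; θ = 1 is an
exact uniform null). Expression is log-normal FPKM: each target's
log-expression loads on its TF's latent factor with loading λ (default
0.9) plus independent noise, so the TF–target Spearman ρ converges to
the bivariate-normal rank correlation (6/π)·asin(λ/2); upregulated genes
additionally receive their drawn log2FC as a case-group mean shift.
Adjusted p-values are assigned by construction (< 0.05 exactly for the
planted set) rather than recomputed, because the DE step is out of
scope. The ortholog map retains each gene with probability 0.7 with 1–3
homologs (0.7/0.2/0.1), roughly the coverage and duplication profile of
human→zebrafish homology. All draws come from one seeded generator;
identical seeds give byte-identical files. The default documentation
seed is 20210330.

What the generator does **not** emulate: count-level noise
(negative-binomial mean–variance), library-size and length biases,
correlated co-regulation beyond a single latent factor per TF, and real
annotation structure in the pathway sets (random sets plus one planted
mostly-upregulated set). Passing simulation tests therefore demonstrate
the statistical machinery — calibration of the null, power at realistic
counts, rank-correlation recovery — not robustness to RNA-seq artefacts.

`table1_fixture` is the deterministic complement: synthetic gene symbols
arranged so that all twelve published per-species (K, k) overlap counts,
the 269/1820 upregulated totals, and the 18-gene overlap between the two
dominant regulons' upregulated targets hold exactly, at configurable
universe sizes (defaults are the calibrated ones). Its ortholog map is
built class-wise — genes are grouped by their membership signature
across the six regulons and up/non-up status, and each zebrafish class
is covered by the matching human class — so transferring the human
regulon database reproduces the zebrafish regulons exactly. This is a
structural stand-in for the original accession-derived data, which the
package deliberately does not bundle.

## Problem sizes in the shipped tests

Oracle equivalence enumerates all valid hypergeometric cases at N ≤ 12
and all rank permutations at n ≤ 8; the type-I-error check uses 500 null
replicates and the power check 200 planted replicates at the default
study-scale counts (no expression matrices are generated for these, as
only the DE stage is exercised); the null-pipeline property uses 50
seeds at a reduced 2,000-gene universe. These sizes were chosen to keep
the full suite comfortably interactive while leaving the binomial error
bars well inside the asserted bands.

## Known limitations

- The regulon catalogue, GO memberships and pathway collections are
  inputs; results inherit their release-specific content, which is why
  externally derived quantities (exact upregulated gene counts, the
  specific enriched-pathway list, the 99-of-136 correlated-target count)
  are covered only structurally.
- Universe calibration assumes the published analysis used an integer
  universe within the scanned range and conventional rounding of p.
- The exact Spearman null assumes exchangeability and no ties; midrank
  handling under heavy ties relies on the t-approximation.
- No partial correlation or covariate adjustment: the correlation stage
  is confirmatory, not causal.
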