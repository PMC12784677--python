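# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generator, and the numerical and design choices behind the
`heterosis` package.

## Problem setting

A reciprocal hybridization experiment produces four genetic groups — two
purebred parental lines and two reciprocal hybrids — grown under shared
conditions and profiled by bulk RNA-seq with a few biological replicates per
group (the package requires at least two; four is the design it is tuned
for). The scientific questions are (i) which genes are differentially
expressed between hybrid and parents, (ii) how hybrid expression is inherited
— additively (tracking the mid-parent value), by expression-level dominance
(tracking one parent), or transgressively (outside the parental range) — and
(iii) which functional gene sets are over-represented among the non-additive
genes, the fraction of the transcriptome usually invoked to explain hybrid
vigor. Alongside the transcriptome the package computes the standard
phenotype statistics of an aquaculture grow-out (specific growth rate,
survival, enzyme specific activity, intestinal histomorphometry, 2^−ΔΔCT
relative qPCR expression, one-way ANOVA + Tukey HSD).

## Normalization

Library sizes are corrected with median-of-ratios size factors: genes with a
zero in any sample are excluded from the geometric-mean reference; each
sample's factor is the median ratio of its counts to the per-gene geometric
means; factors are rescaled to geometric mean 1. If no gene is expressed in
every sample the code falls back to total-count scaling and logs a warning.
FPKM and TPM conversions are provided for reporting
(FPKM = c·10⁹/(L·colsum); TPM renormalizes the per-length rates to 10⁶ per
column). All testing happens on size-factor-normalized counts, not FPKM/TPM.

## Differential expression

Each pairwise comparison uses a negative-binomial likelihood-ratio test.
Per gene, a single dispersion α is estimated by pooled method-of-moments:
α = max((s² − m)/m², 10⁻⁸) with m the grand mean of the normalized replicates
and s² the pooled within-group variance (α = 0 when the gene is all-zero; no
shrinkage toward a mean trend, by design — the estimator is simple and fully
testable). The null model fits one common mean, the alternative one mean per
group; with α fixed, the NB mean MLE is the sample mean, so the statistic has
a closed form evaluated through the gamma-function likelihood (valid for the
real-valued normalized counts).

**Reference distribution.** The asymptotic χ²(1) reference is badly
anticonservative at the design sizes this package targets: with n = 4 per
group, the plug-in dispersion is estimated from 6 residual degrees of
freedom, and genes whose dispersion happens to be underestimated produce
astronomically small p-values. In complete-null simulations (2000 genes, 4v4)
essentially every run yielded BH discoveries at q < 0.05 under χ²(1). The
statistic is therefore referred to F(1, n − 2) — a quasi-likelihood-style
small-sample calibration that absorbs the dispersion-estimation uncertainty
and converges to χ²(1) as replication grows. Under this reference the
complete-null false-discovery proportion is controlled (measured 0.00–0.07
against a nominal 0.05 across seed blocks), and the p-values agree with a
1000-permutation oracle of the same statistic within 0.05 absolute from about
8 replicates per group (the package's oracle fixture uses 12). *Known
limitation:* at n = 4 the F reference is conservative for weakly expressed
genes — a planted 4-fold change at dispersion 0.05 is detected at p < 0.01
for ~90% of genes rather than the ~100% an uncalibrated χ² would claim, and
exact agreement with a permutation null is not achieved at n = 4 by either
reference.

Fold changes are log₂((mean_b + 1)/(mean_a + 1)); the pseudocount of 1
normalized count stabilizes low-expression genes. A DEG satisfies
|log₂FC| > 1 and BH-FDR < 0.05, both strict, with the multiple-testing family
being all genes of one comparison. Genes all-zero in both groups get p = 1;
non-finite statistics get p = 1 with a logged flag, never silent omission.

## Inheritance classification

The classification universe is the union of DEGs across the three pairwise
comparisons (hybrid/parent1, hybrid/parent2, parent2/parent1). Each
comparison contributes a sign in {−1, 0, +1}: the sign of the log₂FC when the
comparison is a DEG, 0 otherwise — (a, b, c) as defined in the README.
Decision order, evaluated per gene:

1. **conserved** if |log₂FC(hybrid/parent)| < 1.25 (strict) against both
   parents;
2. **transgressive** if the hybrid is significantly on the same side of both
   parents (a = b ≠ 0): IX/X for equal parents, XI/XII up, VII/VIII down;
3. **additive (I/II)** if the parents differ (c ≠ 0), the MPV deviation test
   does not reject, and the hybrid mean lies inside the closed parental
   interval; I when parent 2 is the high parent, II otherwise;
4. **expression-level dominance (III–VI)** for the dominance sign patterns
   (hybrid indistinguishable from one parent, significantly different from
   the other, parents different);
5. **ambiguous** for everything else — including the "between parents yet
   significantly off-MPV" combination, which no named class absorbs.

The MPV deviation test is a two-sided one-sample t of log₂(replicate + 1)
against log₂(MPV + 1) at α = 0.05, with a zero-variance convention (p = 0 or
1 according to whether the means differ beyond 10⁻⁹ relative). Making
additivity hinge on the MPV test — rather than requiring both hybrid-parent
comparisons to be individually significant — is a deliberate design choice
with a mathematical justification: a hybrid at the exact arithmetic MPV of
parents R-fold apart differs from the high parent by |log₂((1+R)/(2R))| < 1
for *every* R, so under a |log₂FC| > 1 DEG rule the "significant in both
directions" signature is unreachable for truly additive genes, and any rule
demanding it would systematically misfile additive genes as dominant. The
planted-truth simulations confirm the choice: with the MPV gate the pipeline
recovers the additive vs non-additive category for ~90% of classified genes
and reports a non-additive fraction within a few points of the planted one;
with a pure sign-triple rule both numbers degrade to structural failure.

Parent-swap symmetry (relabel parent1 ↔ parent2, i.e. swap a/b and negate c)
permutes labels exactly as I↔II, III↔VI, IV↔V, VII↔VIII, XI↔XII with IX and X
fixed — low-parent dominance maps to low-parent dominance, as the class
semantics require. This is asserted on random triples in the test suite.

`summarize_patterns` reports per-class counts and percentages rounded half-up
to one decimal; the additive/non-additive denominator excludes conserved and
ambiguous genes, which are reported separately. Note that published splits
rounded to sum to 100 cannot always be reproduced by any positional rounding
of the underlying ratios (e.g. 969/7475 = 12.96% prints as 13.0, not 12.9).

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k | N, K, n) via `scipy.stats.hypergeom.sf` (verified against exhaustive
enumeration for all N ≤ 20). Terms are intersected with the universe before
size filtering (defaults 5–2000); BH runs across surviving terms only, one
collection at a time, so GO- and KEGG-style collections are corrected
separately. The default universe is every gene with a nonzero count in at
least one sample. Output order is deterministic: (p, term_id).

## Assay statistics

SGR = 100·(ln x₂ − ln x₁)/T in %/day for length or weight; survival, specific
activity, villus density and fold/crypt ratio are the obvious ratios with
strict domain checks. One-way ANOVA uses the classical between/within
decomposition with the conventions F = 0, p = 1 for all-identical data and
F = ∞, p = 0 for zero within-group variance with distinct means. Tukey HSD
computes q = |Δ|/√(MSW/2·(1/nᵢ + 1/nⱼ)) (Tukey–Kramer under imbalance) with
p from `scipy.stats.studentized_range` (numerical evaluation; cross-checked
against `scipy.stats.tukey_hsd` and the published 5% point q(4, 12) = 4.199).
The compact letter display uses the insert-and-absorb algorithm with letters
assigned in descending-mean order, matching the "a, b, c" convention of
growth-trial tables. Growth curves are summarized non-parametrically (group
mean ± SD per timepoint); no parametric curve is fitted.

## Synthetic data

`simulate_hybrid_counts` emulates the downstream structure of the motivating
experiment: 4 groups (P1, P2 and reciprocal hybrids H1, H2), 4 replicates
each (16 libraries), NB counts at a target depth of 10⁶ per library,
dispersion 0.05, baseline means log-normal (log₂ mean 6, log₂ SD 1.5).
Default planted modes: 20% conserved, 20% additive, 15% + 15% parent-
dominant, 15% + 15% over/under-dominant; non-conserved genes separate the
parents by ±2 log₂ units (sign random per gene); over/under-dominant hybrids
sit 1 log₂ unit beyond the extreme parent — chosen to be detectable at n = 4
and α = 0.05 while deliberately sitting at the strict DEG boundary in
expectation, so transgressive genes are recovered as non-additive but split
between transgressive and dominance labels. Reciprocal hybrids share the
planted truth and differ only in sampling noise. `truth.attrs["group_scale"]`
records the planted-mean-to-raw-count factor per group so tests can undo the
depth scaling. All generators are pure functions of their arguments
including the seed.

What the generator does *not* emulate: batch effects, GC/length bias,
mean-dependent dispersion trends, outlier replicates, and unbalanced
designs. Passing the planted-truth tests therefore demonstrates correctness
of the inferential machinery under the stated model, not robustness of the
pipeline to real-data artifacts.

`simulate_growth_cohort` draws per-fish log-normal noise (given CV) around
stylized group trajectories in which both hybrids outgrow both purebreds;
`simulate_gene_sets` plants one term with a specified query overlap among
random terms.

## Numerical choices and degenerate inputs

- Dispersion floor 10⁻⁸ (keeps 1/α finite); α = 0 convention for all-zero
  genes; p = 1 for all-zero or non-finite-statistic genes.
- log₂FC pseudocount 1; MPV test on log₂(x + 1); zero-variance conventions as
  stated above.
- Strict inequalities at every published threshold (DEG |log₂FC| > 1,
  FDR < 0.05, conserved < 1.25, MPV α < 0.05): boundary values do not call.
- Percentages rounded half-up to 1 decimal via exact decimal arithmetic.
- Enrichment ties broken by term id; studentized-range p clipped to [0, 1].
- Pipeline size factors are computed once on the full matrix so the three
  pairwise tests and the MPV share one normalization.

## Problem sizes used in the checks

The planted-truth check runs 5000 genes × 16 samples; null-calibration
checks use twenty 2000-gene simulations; the permutation oracle uses 20
genes × 12 replicates/group × 1000 permutations; enumeration checks cover
every hypergeometric configuration with N ≤ 20. The whole acceptance script
completes in a few seconds on one CPU.

## Known limitations

- Single-factor designs only: no covariates, no replicate-free mode, no
  shrunken fold changes.
- The F(1, n−2) calibration is conservative at n = 4 for low-count genes
  (see above); users with very few replicates should treat borderline
  q-values cautiously.
- The 12-pattern taxonomy assumes one hybrid group per analysis; reciprocal
  hybrids are analyzed separately against the same parents.
- GO DAG structure, cross-species identifier mapping and pathway topology
  are out of scope; the enrichment module consumes flat GMT files.
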