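# Methods

## Model and procedure

`permde` tests for differential expression between two small groups of
bulk RNA-seq samples quantified as FPKM. The analysis chain is:

1. **Expression filter.** A gene is "expressed" when its FPKM exceeds 1 in
   at least one sample. The inequality is strict so the boundary is
   deterministic; the filter acts on the raw FPKM scale before any
   transformation and is idempotent.
2. **Log transform.** x = log2(FPKM + 1), mapping FPKM 0 → 0 and keeping
   all values nonnegative.
3. **Quantile normalization.** Classic sort–average–reassign: the k-th
   smallest value in each sample is replaced by the mean over samples of
   the k-th smallest values. Ties within a sample (common for clipped
   zeros) receive the mean of the reference values at the tied ranks, the
   standard published convention. Consequences worth knowing: after one
   pass all samples share an identical multiset of values *exactly* when
   the input is tie-free; with ties, tie-group averaging makes per-sample
   multisets agree only up to the tied ranks, and a second pass is the
   identity only when all samples share the same tie pattern. The full
   filtered matrix is normalized once, jointly over both groups.
4. **Pooled-variance t.** Per gene,
   t = (x̄_T − x̄_C)/√(s²_p(1/n₁+1/n₂)), with the pooled variance floored
   at 1e-8 so rows made exactly equal by quantile normalization stay
   finite (a Welch variant is a config switch; for equal group sizes the
   two coincide).
5. **Pooled permutation null.** Group labels are reassigned B = 1,000
   times, uniformly with replacement over all assignments that preserve
   the group sizes (the identity is not excluded); |t| is recomputed for
   every gene under every reassignment and pooled across genes and
   permutations into one sorted empirical null. An exhaustive mode
   enumerates all C(n, n₁) distinct assignments (20 for 3 vs 3) and is the
   exactness oracle for the sampled mode. The null is pooled rather than
   per-gene because 20 assignments per gene cannot produce p < 0.05.
6. **Empirical p.** Two-sided, add-one smoothed:
   p = (1 + #{|t*| ≥ |t|})/(1 + N). Smoothing guarantees p ∈ (0, 1],
   monotone non-increasing in |t|, and valid under the null.
7. **Adjustment.** Benjamini–Hochberg step-up on the empirical p-values by
   default; a plugin permutation-FDR — mean pooled-null exceedances per
   permutation divided by observed exceedances, made monotone by a
   cumulative minimum — is available as `adjust_method="perm-fdr"` for
   sensitivity analysis.
8. **DEG call.** p_adj < alpha (default 0.05, strict) *and*
   |log2FC| > cutoff (strict), where log2FC is the difference of group
   means on the normalized log2(FPKM+1) scale. The cutoff is the 95th
   percentile (linear interpolation) of |log2FC| over expressed genes in
   percentile mode, or a fixed value (default 0.336 ≈ 1.26-fold) in fixed
   mode. Both modes exist because a reported "5% percentile" anchor for a
   fixed 0.336 threshold is ambiguous between the two readings.
9. **EASE enrichment.** For each gene set (GMT), members are intersected
   with the universe — defined as the expressed genes scored by the DE
   stage, not the whole genome — and the overlap with the DEG list is
   scored by the one-sided Fisher exact (hypergeometric upper-tail) p and
   by the EASE score, the same tail with the overlap reduced by one
   (`max(k−1, 0)`), which penalizes sets supported by very few genes and
   satisfies ease_p ≥ fisher_p with equality at k = 0. Tails are computed
   by explicit summation of the hypergeometric mass in log space
   (`gammaln`-based log-pmf, `logsumexp` accumulation), so they remain
   accurate for arbitrarily large universes and far tails. Selection is at
   raw EASE p < 0.05 across sets, uncorrected, matching common practice
   for this statistic; BH across sets is an option that defaults off.

## The discreteness floor of pooled nulls at n = 3 vs 3

A fact that shapes every result at this design size: a random
label reassignment reproduces the original grouping (or its mirror) with
probability 2/C(6,3) = 1/10, so in expectation each gene contributes
≈ B/10 copies of its *own* |t| to the pooled null. Hence the i-th smallest
empirical p-value satisfies p(i) ≳ i/(10m) over m genes, and the plugin
FDR estimate is bounded below by ≈ 0.1 at every threshold. Two
consequences:

- Benjamini–Hochberg at 0.05 on pooled empirical p-values rejects
  *nothing* in a 3 vs 3 design, for any effect size — the BH line
  0.05·i/m lies strictly under the attainable p(i). The same bound holds
  for the permutation-FDR switch at any alpha below ≈ 0.1.
- Adjusted thresholds only become meaningful once C(n, n₁) is large
  (n = 4 vs 4 gives 70 assignments, 5 vs 5 gives 252), or at relaxed
  alpha. The unadjusted empirical p-values themselves are well calibrated
  (verified to 3 binomial standard errors at alpha ∈ {0.01, 0.05, 0.10} on
  a 5,000-gene global null) and are the quantity to interpret at n = 3.

This is a property of the method as specified, not an implementation
artifact; the package implements the stated procedure faithfully and the
recovery benchmarks report what it actually achieves. Excluding the
identity-equivalent assignments softens but does not remove the problem
(the null stays contaminated by the planted genes' partial splits), and
the fold-change gate does not rescue it: the percentile cutoff by
construction caps sensitivity at (1 − percentile)/frac_de when the planted
fraction exceeds 1 − percentile.

## Synthetic data: what it emulates and what it does not

The generator mirrors the motivating study design: two groups of 3,
5,000 genes, lognormal-like expression (log2-scale baselines
Normal(4, 2) truncated at 0 — dynamic range roughly FPKM 0–10⁴), i.i.d.
replicate noise of s.d. 0.5 on the log2 scale, 10% of genes carrying an
additive ±2 log2-unit shift with Rademacher sign, and 10% of genes forced
below the expression filter (all FPKM uniform in [0, 0.5]). Defaults are
the package's reference conditions; none are estimates fitted to any
particular dataset, since the motivating study deposits none.

A single seeded generator stream is consumed in a fixed order (gene roles,
effect signs, baselines, noise matrix, silent values), making every output
byte reproducible from one integer.

The truth table's `is_silent` flag records the *realized* below-filter
status: the designated silent genes plus the small fraction of genes whose
truncated-at-zero baseline and noise leave every sample at or below
FPKM = 1. This keeps the invariant "the expression filter removes exactly
the silent genes" true by construction, at the cost that `frac_silent` is
a lower bound on the realized silent fraction (typically ~10% vs ~13% at
the defaults).

What the generator does *not* model, and hence what passing benchmarks do
not certify for real data: per-gene dispersion differences (noise is
homoscedastic on the log scale; real data's mean–variance trend is where
pooled nulls gain or lose the most), gene–gene correlation (all genes are
independent, so binomial error bars on calibration fractions are exact
rather than optimistic), library-size or composition effects (FPKM is
taken at face value; no count-level sampling), and annotation noise in
gene sets (planted sets overlap truth cleanly).

Companion gene sets: a designated quarter of the sets draws 80% of its
members from planted DE genes (without replacement) and the rest from
non-DE genes; the other sets draw uniformly from all genes.

## Numerical and design choices

- **Canonical sample order.** The estimator reorders samples by (group,
  sample id) before consuming randomness, so results are invariant to the
  order in which samples are supplied at a fixed seed.
- **Tie-breaks in the output table.** Rows sort by p_adj, then |log2FC|
  descending, then gene id — fully deterministic.
- **Variance floor** 1e-8 (log2-scale variance): only reached by exactly
  tied rows; alters no realistic t value.
- **Percentile computation** uses linear interpolation between order
  statistics (`numpy.quantile` default).
- **Hypergeometric scans.** `upper_tail_grid` evaluates all (n_deg, k)
  tails at a fixed universe and set size in one vectorized pass,
  accumulating each support row from its top so far-tail values keep full
  relative precision; double-precision mass underflows for universes
  beyond ~1000, where the scalar log-space path remains valid.
- **Group labels** in the interchange format are exactly `control` and
  `treated`; the estimator itself accepts any two labels and treats the
  sorted-first label as the reference group.
- **Error taxonomy.** Configuration violations raise `ConfigurationError`
  (CLI exit code 2); an empty filter result raises `EmptyResultError`
  naming the threshold; malformed GMT lines raise `GmtParseError` with the
  line number. Existing CLI outputs are never overwritten without
  `--overwrite`.

## Benchmark scales

The shipped checks run at: 5,000 genes × 1,000 permutations for null
calibration and effect recovery (seconds each, vectorized); 200 genes ×
2,000 sampled vs 20 exhaustive assignments for the oracle comparison; an
exhaustive tail scan of all ~7×10⁷ valid count configurations with
universe ≤ 200 against an independent log-factorial summation oracle plus
a `scipy.stats.hypergeom` spot sample; 100 random matrices for the
normalization invariants; and two full CLI runs compared byte-for-byte.

## Known limitations

- Two-group, unpaired designs only; no covariates; no count-model
  (negative-binomial) testing — FPKM is the contract boundary.
- The pooled null assumes a common null |t| distribution across genes;
  under strong heteroscedasticity per-gene standardization would be
  preferable and is not implemented.
- At n = 3 vs 3, adjusted-p thresholds below ~0.1 are unattainable by
  construction (see the discreteness floor above); the package reports
  this honestly rather than working around it.
- EASE significance is uncorrected across sets by default (mirroring
  standard use of the statistic); with many sets, enable the BH option.
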