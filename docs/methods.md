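# Methods

## Per-SNP association scan

Each SNP is tested by additive logistic regression of case status on the
minor-allele count with covariates (age by default; sex optional).  The
reported statistic is the Wald chi-square on the genotype coefficient
(1 df), the convention of standard GWAS tooling, so `T` and `P` are linked
by the upper χ²₁ tail.  Minor-allele coding is decided from the whole
cohort's allele frequency; ties at 0.5 keep the input coding.  Note that
for a simulated causal SNP whose cohort frequency crosses 0.5 (case
enrichment can push it over), the scan's recoding flips the sign of the
fitted coefficient relative to the simulated one —
`gwas_assoc.minor_allele_flips` exposes the mask so recovery checks can
compare sign-matched effects.

Fitting is Newton/IRLS with a convergence tolerance of 1e-8 on the
maximum coefficient change and a 100-iteration cap.  Because the
permutation engine refits every SNP under hundreds of label permutations,
the kernel is a fused per-SNP Newton solver (compiled with numba when
available; a vectorized numpy path implements the identical algorithm and
is cross-checked against it and against a reference logistic
implementation in the tests).  Degenerate SNPs — monomorphic, separated
(detected by a one-dimensional quasi-separation scan plus a diverging
coefficient guard at |b| > 15), or non-converged — are flagged and
assigned `P = 1`, `T = 0` rather than dropped, so set-level denominators
stay defined; flags are propagated to the output.

The genomic inflation factor is `λ = median(T) / 0.4549…` over
non-degenerate records.

Label permutations shuffle case/control status across all individuals
while covariates stay attached to their individuals, conserving the case
count exactly; the same replicate set feeds both permutation-based
set-level tests, so their nulls are computed on identical reshuffled data.

## SNP-to-gene mapping and gene statistics

A SNP belongs to a gene when its position lies in the closed interval
`[start − 20 kb, end + 20 kb]` (1-based) on the same chromosome, strand
ignored; assignments are many-to-many.  Each covered gene is summarized by
its most significant mapped SNP (minimum p; ties broken by larger
chi-square, then lexicographically smaller SNP id).  Genes with no mapped
SNP are excluded from all analyses: they can never contribute signal, and
including them would distort the SNP-resampling null.

## Gene sets

GMT collections are read with duplicate members collapsed and empty tokens
dropped.  The size filter retains sets of 5–250 genes measured on the
annotated membership, not on the genotype-covered subset; covered counts
enter later through the mapping.  Genes in a set but absent from the
annotation stay in the set definition and simply contribute nothing.

## The four set-level tests

**GenGen-style running sum (competitive).**  Weight exponent τ = 1 by
default (configurable): with τ = 1 the score is invariant to rescaling all
gene statistics.  The enrichment score is the maximum (positive-deviation
convention) of the running sum, which provably returns to zero after the
last gene.  If every hit weight is zero (all-degenerate permutation), hit
increments fall back to `1/N_H`.  Per permutation replicate the gene
statistics and the full ranking are recomputed, keeping the gene universe
fixed.  Sets covering no ranked gene are flagged; a set covering the whole
ranking is an error (the miss decrement is undefined).

**ALIGATOR-style SNP resampling (competitive).**  Significant genes are
those with ≥ 1 mapped SNP at `P < 0.05` (strict).  Replicates draw SNPs
uniformly without replacement, marking every gene a drawn SNP maps to,
until the distinct significant-gene count reaches the observed total; if
the final multi-gene SNP overshoots, surplus genes are dropped uniformly
among the ones that SNP just added, so every replicate matches the target
exactly.  The empirical p uses ≥ with add-one smoothing — a deliberate,
conservative reading of "more significant genes than observed" that can
never return zero.  By matching the significant-gene count, the null
shares the observed gene-size and SNP-density profile, which is the
method's defense against density bias (verified by a dense-gene type-I
test in the suite).

**SNP ratio test (self-contained).**  The statistic is `m_sig / M` over
the set's mapped SNPs, deduplicated at set level (a SNP inside two member
genes counts once — the paper-trail convention adopted here; the monotone
equivalence with a significant:nonsignificant odds form means p-values are
unchanged).  The permutation p recomputes the ratio from the shared
permuted scans.

**Hierarchical mixed model (self-contained).**  Association p-values are
transformed back to χ²₁ deviates, and each set is fitted with the one-way
random-intercept model `y_ij = β0 + g_j + ε_ij` (gene effects
`g_j ~ N(0, σ²_g)`).  The model is fitted by REML with the likelihood
profiled down to the variance ratio `λ = σ²_g/σ²_e`, minimized on a
bounded log grid; `λ = 0` is compared explicitly so the boundary (no
between-gene variance) falls back to the pooled OLS solution.  The test is
the one-sided Wald z of `H0: β0 = 1` versus `β0 > 1`, since a 1-df
chi-square has mean 1 under no association; constant input (all `y = 1`)
yields `β0 = 1`, zero variances and p = 0.5 by convention.  The choice of
a Gaussian linear model on the chi-square scale, the null value 1, the
one-sided alternative and the normal reference are modeling decisions:
the outcome is skewed, so the normal Wald reference is only asymptotically
calibrated — the suite checks that the empirical one-sided size at 0.05
stays within [0.02, 0.09] for 20 genes × 10 SNPs, and grouping by gene is
what protects the test from counting within-gene SNPs as independent
evidence.  A SNP mapped to several member genes contributes one row per
gene.  Sets with fewer than two covered genes are flagged, not fitted.

## Integration

Per-method raw p-values get Benjamini–Hochberg step-up adjustment.
`bh_adjust` accepts a denominator `m_total` larger than the supplied list
so a published top list can be adjusted against the full number of tests
it came from; the step-up minimum then runs over the supplied ranks only.
The consensus report takes K = the largest per-method count of sets at
FDR < 0.05 (floored at 1), collects each method's top-K by raw p (ties by
set name), and annotates the union with how many methods found each set.
Contributing genes are members with ≥ 1 SNP at `P < 0.05`; the enriched-
gene table lists genes recurring in at least 4 top sets with their
significant/total SNP counts and best SNP.  The leave-one-out helper
reruns a single method on a set minus one gene, everything else fixed.
Bundled published top-9 tables (`gwasea.datasets`) carry their FDR values
as printed, because FDRs computed over all 1,331 original tests are not
recoverable from a top list alone.

## Synthetic data

The generator emulates the structure the analysis assumes rather than any
particular genome: genes laid out per chromosome with uniform lengths
(5–50 kb) and gaps (30–120 kb); SNPs scattered Poisson per gene inside the
±20 kb windows (coverage guaranteed) plus ~10% intergenic; minor-allele
frequencies uniform on [0.05, 0.5]; GO-like sets of 5–25 genes drawn with
a shared pool so ~30% of members recur across sets (disjoint construction
when the overlap fraction is 0).  Cohorts are sampled from
`logit P(case) = α + Σ β_i g_i + γ·age` with genotypes binomial(2, maf),
ages uniform on 3–12 years and γ = 0 by default; α is computed
analytically from the target prevalence and individuals are accepted by
rejection until the exact case/control counts are reached.  Genotypes are
independent across SNPs by default; an optional block-LD mode correlates
SNPs within positional windows (default 100 kb) by copying the block
leader's genotype with a configurable probability.  Missing calls can be
injected at a configurable rate (default 0).

Two reference scenarios are used throughout the tests and the acceptance
script:

- **Null calibration** — 537 cases / 605 controls (the shape of the
  motivating caries cohort), 200 genes at ~10 SNPs/gene (~2,000 SNPs),
  100 sets, B = 200 permutations, no effects.  Every method's raw
  set-level p-values must have empirical size at 0.05 inside the binomial
  99% band, λ must be near 1, and FDR < 0.05 discoveries near zero.
- **Power/positive control** — 1000 + 1000 individuals, one implanted
  causal set with 5 causal genes carrying one causal SNP each at per-SNP
  odds ratio 1.6.  This scenario uses tag-SNP density (~3 SNPs per gene,
  as in an LD-pruned panel) and draws causal-set sizes from
  [5, 10]: a positive control is a set whose membership is substantially
  causal.  With ~10 SNPs per gene the baseline probability that a null
  gene contains a significant SNP is ≈ 0.4, which mathematically caps the
  resolution of the gene-count methods regardless of effect size — at tag
  density all four methods rank the causal set first or second across
  seeds.  B = 200 permutations (and 10× that many SNP resamples,
  preserving the 10,000:1,000 ratio of the full-scale design) keep the
  run inside a few minutes; the full-scale defaults in the code are 1,000
  permutations and 10,000 resamples.

What the generator does *not* emulate: realistic human LD maps and
haplotype structure, allele-frequency spectra, sex chromosomes,
population stratification, genotyping error and study-level QC artifacts.
Passing calibration and power checks on these synthetics therefore
demonstrates the correctness and internal consistency of the statistical
machinery, not performance on real cohorts.

Because the per-SNP scan is marginal, estimates of a causal SNP's
log-odds are attenuated slightly by the omitted other causal SNPs
(logistic non-collapsibility; ≈ 0.4 standard errors under the power
scenario).  The recovery check therefore uses a 3-SE band, which absorbs
this known bias.

## Numerical conventions

- Empirical p-values always use add-one smoothing; they live in
  [1/(B+1), 1] and are never zero.
- Ties are broken deterministically everywhere (gene ranking by id, best
  SNP by larger T then id, top lists by set name), so repeated runs are
  bit-identical for a fixed seed.
- All randomness flows from `numpy.random.SeedSequence` spawns of a
  single user seed.
- Report tables round to 3 decimals only at the display/export layer.

## Known limitations

- The mixed model's analytic p can be anticonservative for very small
  sets (few genes, few SNPs) because the Wald reference ignores the
  skewness of chi-square outcomes; the permutation-based tests do not
  share this caveat.
- ALIGATOR's empirical p has resolution 1/(B+1); at B = 200-2,000 small
  p-values saturate at the floor.
- The scan handles missingness per SNP (complete-case within SNP) and
  flags rather than models separation; no imputation or relatedness
  correction is attempted.
- `bh_adjust` with `m_total` above the list length is exact only when the
  omitted p-values are larger than the supplied ones (true for a top
  list), which is the use it is intended for.
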