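# Methods

This note documents the statistical models implemented in `rvpath`,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical decisions that affect
results.

## Gene-level tests

### Weighted-sum (WS) rank test

For a group of variants (a gene, or the pooled SNPs of a set), each
variant *i* is weighted by the standard deviation of its allele count
under the **unaffected-sample** frequency with add-one smoothing:

    q_i = (m_i^U + 1) / (2 n_i^U + 2)
    w_i = sqrt(n_i · q_i · (1 − q_i))

where `m_i^U` is the minor-allele count among the `n_i^U` genotyped
unaffected individuals and `n_i` the total genotyped at *i*. Each
individual's genetic score is `γ_j = Σ_i g_ij / w_i` (missing dosages
contribute 0; they are also excluded from the `q` and MAF
denominators). The statistic is the sum of midranks of γ over affected
individuals. Rare alleles get small `w_i`, hence large weight — the
design that makes a burden of many weak rare effects detectable.

Significance is by phenotype permutation: labels are shuffled and
**everything** — q, w, γ, ranks — is recomputed, because the weights
depend on who is unaffected. The p-value uses the add-one estimator
`p = (1 + #{x* ≥ x_obs}) / (B + 1)`, which is never zero (Fisher
combination downstream needs p > 0) and gives a valid level-α test. An
`exhaustive=True` mode enumerates all distinct case/control relabelings
for small samples and returns the exact permutation proportion; the
test suite checks it against an independent enumeration oracle.

Default `B = 1000` for standalone gene tests; the evaluation harness
uses 200 (granularity 1/201 ≈ 0.005, sufficient for rates measured at
α ≥ 0.005 while keeping full-study runs on one CPU tractable).

### Combined multivariate collapsing (CMC)

Variants with MAF below `rare_threshold` (default 0.05, the common
collapsing convention; configurable) are collapsed into a binary
"carries any rare minor allele" indicator per collapsing unit — per
gene by default, or one indicator for a whole set with
`grouping='set'`. Common variants keep their dosage columns. Case and
control mean vectors of this design are compared with Hotelling's T²,

    T² = (n₁n₂/(n₁+n₂)) d' S_pooled⁻¹ d,
    F  = T² (n₁+n₂−p−1) / (p(n₁+n₂−2)) ~ F(p, n₁+n₂−p−1).

Constant columns are dropped (with a warning); a singular pooled
covariance falls back to the pseudo-inverse with degrees of freedom set
by the matrix rank. A group with no non-constant columns has no defined
test; see the Fisher note below for how that propagates.

## Pathway-level methods

All aggregation methods operate on the per-gene score profile
`s_g = −log p_g` from one gene-level method (WS or CMC) on one
phenotype replicate.

- **Fisher's method**: `X² = −2 Σ ln p_g ~ χ²(2k)` over the k genes of
  the set. Genes whose gene-level test is *undefined* (no testable
  variation) are excluded and the degrees of freedom reduced: a hard
  p = 1 is not a draw from the null, and including such genes measurably
  deflates the type I error of the combined test (0.036 instead of
  0.05 in the null-calibration study). For KS and GSEA profiles the
  same genes simply carry score 0.
- **KS**: two-sample Kolmogorov–Smirnov statistic between in-set and
  out-of-set scores. The two-sided p uses the finite-n Kolmogorov
  distribution at the effective sample size `n₁n₂/(n₁+n₂)` (the plain
  limiting form is visibly conservative at set size 25: 0.037 measured
  at nominal 0.05). The default alternative is **'greater'** (in-set
  scores stochastically larger, Hodges-corrected tail bound): a
  pathway screen asks about enrichment, and a two-sided test also
  rejects sets *depleted* relative to a signal-contaminated background,
  which inflates its apparent type I error on clean sets whenever the
  experiment contains truly associated genes. `--ks-alternative`
  restores the two-sided or 'less' variants.
- **GSEA (weighted KS)**: genes are ranked by score descending (ties
  broken by gene id for cross-platform determinism); walking the list,
  in-set genes add `s^α / Σ_in-set s^α` and out-of-set genes subtract
  `1/(N − |set|)`; the enrichment score is the signed running-sum value
  of maximal absolute deviation (earliest position on fp-level ties).
  Weight exponent α defaults to 1 (the standard weighted statistic);
  α = 0 recovers the classic unweighted KS running sum. If all in-set
  scores are 0 the hits are weighted uniformly. Significance is by
  phenotype permutation with the **entire profile recomputed** per
  shuffle, one-sided on ES* ≥ ES_obs.
- **Direct tests**: WS on the pooled variants of the set; CMC with
  per-gene collapsing by default (one indicator per gene plus common
  dosage columns) or whole-set collapsing on request.

## Evaluation harness

`evaluate_methods` computes a p-value for every (set, method,
replicate), rejection rates at the requested α levels, and per-set
best-method calls (most significant replicates at α = 0.05; ties
reported together, and a tie including WS counts as "WS best" in the
regression outcome).

Gene-level results are computed once per replicate and shared across
all sets and aggregation methods. Two structural optimizations keep a
full eight-method study on one CPU:

- **Shared permutation pool.** Within one replicate, the observed
  phenotype, every GSEA outer shuffle, and every direct WS set test
  have the same number of cases, so the permutation null distribution
  of the WS rank sum is identical for all of them. One pool of B
  relabelings per replicate therefore prices all WS p-values of that
  replicate; the standalone `ws_test`/`gsea_test` functions keep the
  literal fresh-permutations contract.
- **Batched Hotelling.** CMC designs depend only on genotypes, so the
  per-gene and per-set designs are built once and the T² p-values for
  many phenotype columns are computed in one batched solve.

The spurious-gene filter consumes the same gene-level results: a
noncausal gene is flagged when the number of replicates in which
**both** WS and CMC give p < 0.05 strictly exceeds a count threshold
(default 15 of 200 replicates; scaled proportionally for shorter runs,
e.g. >3.75 → 4 of 50). A `marginal` mode requiring each method's own
count to exceed the threshold is available; the joint reading is the
default as the stricter interpretation. The filter never flags a causal
gene, by construction.

Set construction mirrors the four-category evaluation design: for each
C in {5, 10, 15, 20, 25}, 100 sets of C causal + (25 − C) noncausal
genes; 500 all-noncausal (null) sets; 500 null sets drawn from
nonspurious noncausal genes; and the 500 category-1 sets with their
noncausal members redrawn from the nonspurious pool (causal draws
reused, matching the "modified" construction). Sampling is without
replacement within a set, deterministic given the seed.

`best_method_regression` fits a maximum-likelihood logistic model of
"WS is (among) the best method(s)" on five set features: number of
causal genes, number of causal SNPs, total SNPs, average per-gene
summed causal-SNP MAF, and the weighted risk score `Σ MAF·β` over the
set's causal SNPs. Complete separation falls back to a
ridge-penalized fit, flagged in the report (no standard errors).

## Synthetic mini-exome generator

The generator emulates the *structure* of a mini-exome case/control
resource: by default 697 unrelated individuals, ~3,205 genes with a
mean of 7.6 SNPs each, a MAF spectrum with floor 7.17×10⁻⁴, 160 causal
SNPs in 36 genes, and 200 dichotomous phenotype replicates simulated on
one fixed genotype matrix.

Specifics and rationale:

- **MAF spectrum**: Beta(0.2, 2.0) rescaled to (floor, 0.5]. The shape
  is a package choice producing a rare-dominated spectrum consistent
  with the printed MAF range; both shape parameters are configurable.
- **Genotypes**: two independent allele draws per individual
  (Hardy–Weinberg), variants independent.
- **Effect sizes**: β = `effect_scale`·|log₁₀ MAF| on the log-odds
  scale (default scale 0.4), the canonical rarer-is-stronger
  architecture; or a fixed β for planted-effect scenarios.
  `causal_maf_range` restricts which variants may be causal (e.g. to
  plant a few strong common effects).
- **Disease model**: additive logistic,
  `P(affected) = logistic(β₀ + Σ β_i g_ij)`, with β₀ calibrated by
  monotone root bracketing so the population mean matches the target
  prevalence (default 0.3) to 10⁻⁶. Replicates are independent
  Bernoulli draws on the same genotypes.
- **Spurious association**: `ld_spurious_genes` noncausal genes have
  each variant column replaced by a copy of a random causal SNP column
  with per-allele flip probability 1 − `ld_fidelity`. This is a
  deliberately minimal stand-in for gametic phase disequilibrium: it
  produces noncausal genes genuinely correlated with the disease model
  without haplotype machinery.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: linkage disequilibrium beyond the copy
mechanism, population structure and relatedness, unmeasured causal
variants, genotyping error, multi-gene SNP membership (each SNP belongs
to exactly one gene here), covariates, and whatever non-additive or
environment-dependent structure a real disease model has. Results on
this generator demonstrate the statistical behaviour of the methods
under their stated assumptions, not their field performance.

## Routine problem sizes

Routine evaluation runs (`SimulationConfig.desk_scale()`) use 500
individuals, 300 genes averaging 3 SNPs, 36 causal genes with 72
causal SNPs, 50 phenotype replicates, 200 WS permutations and 100 GSEA
outer permutations — dimensions chosen so a complete eight-method
study is a few minutes of one CPU while keeping ≥ 5,000 (set,
replicate) draws behind each measured rate. The full-scale defaults
remain available. Note the desk profile's causal-gene *fraction* (12%)
is far higher than a real exome's (~1%); competitive tests (KS, GSEA)
see a correspondingly more contaminated background there, which is the
regime where their one-sided orientation matters (see above).

## Numerical choices

- Permutation p-values: add-one estimator, one-sided upper tail,
  `≥` comparisons with a 10⁻¹² slack against fp noise.
- Asymptotic p-values floored at 10⁻³⁰⁰ before `−log`.
- Midranks for tied γ scores (permutation-exact either way).
- All randomness derives from one master seed; per-unit streams are
  seeded by (seed, stage, unit, replicate) hashing, so results are
  independent of processing order and parallelization.
- Dichotomous dosage/phenotype validation is strict: values outside
  {0, 1, 2}/{0, 1}, duplicate ids, or a stored MAF off by more than
  10⁻⁹ from the dosages are errors.

## Known limitations

- The nested GSEA permutation (a full profile per outer shuffle) makes
  standalone `gsea_test` expensive; the harness's shared-pool variant
  is the practical route for studies. Inner WS permutation counts below
  ~100 give coarse gene p-values and a warning.
- CMC's asymptotic F is approximate for very sparse indicators (few
  carriers); its gene-level p-values are near-uniform at the desk
  scale but the approximation degrades for singleton-carrier designs.
- The spurious filter's count threshold is calibrated to the replicate
  budget by simple proportional scaling; very short runs (< 20
  replicates) leave it little resolution.
- One gene per SNP is enforced throughout; pathway databases with
  overlapping gene models need pre-flattening.
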