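# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `gwasbench`.

## Genotype simulation

Panels are biallelic SNP dosage matrices (minor-allele counts 0/1/2 with a
single missing sentinel). The generator layers four features of crop
diversity panels:

- **Subpopulation structure.** Each marker draws an ancestral frequency
  uniformly from `maf_range` (default 0.05–0.5); subpopulation frequencies
  follow a Balding–Nichols divergence,
  `p_k ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)`, parameterized by `fst` (default
  0.1, two subpopulations). A Hudson-type estimator applied to the realized
  frequencies recovers `fst` when markers are independent.
- **Linkage disequilibrium.** Markers are placed at ~10 kb mean spacing and
  grouped into physical blocks of `block_len_bp` (default 100 kb, ≈10
  markers). Within a block, each subpopulation carries a small haplotype
  pool (default 8) from which individuals copy two haplotypes; the pool
  bottleneck creates within-block r² that decays to background across block
  boundaries. Blocks with a single marker sample alleles directly from the
  subpopulation frequency, so no spurious drift is added where no LD is
  wanted. Consequence of the design: in multi-marker blocks the pool adds a
  small amount of block-level drift, so realized differentiation there
  slightly exceeds the nominal `fst`.
- **Families.** Individuals are grouped into full-sib families (default
  size 5): per block, two parents draw haplotype pairs and each sib inherits
  one haplotype from each parent, giving the expected sib-sharing structure
  in the kinship matrix.
- **Missingness.** Calls are masked i.i.d. at `missing_rate` (default 0 for
  simulated studies; quality control and LD-kNN imputation handle nonzero
  rates).

Dosage orientation is defined by the realized minor allele; exact-0.5 ties
break toward the lexicographically smaller allele letter, a convention the
HapMap reader shares so round-trips are lossless.

What the generator does **not** emulate: coalescent-exact LD decay,
admixture gradients, selection, inbred-line homozygosity (real soybean
accessions are essentially homozygous; the simulator produces outbred
Hardy–Weinberg genotypes), and the very strong genome-wide structure of real
SoySNP50K/MaizeSNP50 panels. Passing the qualitative benchmarks here shows
the models behave correctly under controlled confounding, not that real-data
significance counts will match any published table.

## Trait simulation

Q causal markers are sampled without replacement; effects default to
standard normal (a geometric-decay option exists). The genetic value is the
dosage-weighted effect sum; the per-observation noise variance is
`r · var(g) · (1−H)/H`, so the line means over r replicates satisfy the
broad-sense formula `H = σ²G / (σ²G + σ²ε/r)`. With the default r = 1 the
phenotype is a single BLUP-like value per line. `h2_target = 0` is rejected
(the noise scale is undefined); `h2_target = 1` returns the noise-free
genetic values. Mean realized `var(g)/var(y)` over 200 replicates tracks the
target within half a percentage point at n = 500, m = 2,000.

## Quality control and imputation

QC applies three disjoint rules in order: monomorphic markers, MAF ≤ 5%
(boundary removed, computed on non-missing calls), missing rate > 10%
(strict). The filter is idempotent. Imputation is LD-kNN: for each missing
call, the k = 5 nearest individuals by 1 − IBS distance over a 20-marker
same-chromosome window vote with inverse-distance weights; the weighted mean
dosage is rounded. Observed calls are never modified; an individual with no
comparable window markers falls back to the marker mode (logged).

## Mixed-model core

REML estimation follows the eigendecomposition approach: with
`K = U S Uᵀ`, the model rotates to independent observations with weights
`w_i = λ s_i + 1`, where `λ = σ²ₐ/σ²ₑ`. The profiled restricted likelihood
is maximized over log₁₀ λ on a 49-point grid spanning ±6, refined by bounded
scalar minimization (tolerance 1e-8), and compared against the λ = 0
boundary. Negative eigenvalues from numerical noise or non-PSD group
summaries are clipped at zero. Rank-deficient fixed-effect designs raise an
error naming the collinear columns.

Marker tests are generalized-least-squares Wald tests in the whitened basis:
the residual variance is re-estimated per marker and the statistic referred
to a t distribution on n − p − 1 degrees of freedom (p = null-design
columns), matching an explicit dense-GLS fit to 1e-6 relative. Markers whose
whitened dosage is numerically collinear with the covariates (residual
squared norm below 1e-10 of the column norm) are flagged inestimable (NaN p)
rather than dropped, preserving marker order. P-values are floored at
1e-300.

Variance components are **not** re-estimated per marker in the MLM, CMLM,
ECMLM and SUPER scans (P3D): the components from the null fit are reused,
which is both standard practice for these models and orders of magnitude
faster. MLMM and FarmCPU re-fit variance components whenever the fixed
effects change.

## The eight models

- **ANOVA** — one-way F across observed dosage classes, df (g−1, n−g). A
  between-class sum of squares below 1e-12 of the total is treated as zero
  so constant phenotypes give p = 1 rather than spurious exact fits.
- **GLM** — intercept + PCs + additive dosage, 1-df t test. With no
  covariates and two dosage classes it reproduces ANOVA exactly.
- **MLM** — GLS scan under VanRaden (default) kinship.
- **CMLM** — individuals clustered by average-linkage hierarchical
  clustering on 1 − K rescaled to [0, 1]; the group count is chosen from an
  8-point grid between 1 and n by null REML; group kinship summarizes all
  member pairs (diagonal included), so g = n reproduces MLM exactly.
- **ECMLM** — enumerates {IBS, VanRaden} × {average, complete, single} ×
  {mean, median, max} over the same group grid and scans under the
  likelihood-best combination. Group summaries are computed with
  segment-reduce operations (mean/max) and a sorted-block median, so the
  full enumeration stays inexpensive.
- **SUPER** — initial GLM p-values are binned (bin sizes 10×, 100× and
  1000× the median marker spacing); the best marker per bin forms the
  pseudo-QTN candidates; (bin size, QTN count) maximize the null REML of a
  VanRaden kinship built from the QTNs (counts 2, 4, 8, 16, 32 capped at
  min(50, √n)). When a tested marker has r² ≥ 0.7 with a pseudo-QTN, that
  QTN is dropped from the kinship for that test; markers sharing an
  exclusion set share one eigendecomposition. An empty post-exclusion QTN
  set falls back to the covariate-only fixed model (logged).
- **MLMM** — forward selection of the most significant marker as a fixed
  cofactor (variance components re-estimated each step) until
  `max_cofactors` (default 10) or the genetic-variance ratio falls below
  0.01, then backward elimination; every visited subset is scored by
  extended BIC (−2·logL_ML + k·log n + 2·log C(m, k), with the ML
  likelihood evaluated at the REML variance ratio) and the best subset is
  reported. Cofactor markers receive substituted p-values from leave-one-out
  fits.
- **FarmCPU** — iterates a fixed-effect scan (current pseudo-QTNs as
  covariates) with a random-effect QTN refresh: FEM p-values are binned at
  three bin sizes, candidates in mutual LD (r² ≥ 0.7) are greedily pruned
  keeping the more significant — without pruning, an LD block straddling a
  bin boundary can yield two correlated QTNs that cancel each other's
  substituted tests — and (bin size, count) maximize the null REML of the
  QTN kinship. Each pseudo-QTN's reported p-value is substituted from a fit
  excluding it from the covariates ("unified"). Iteration stops when the QTN
  set repeats, when no marker reaches the entry threshold 0.01/m (the scan
  then reduces to GLM), or at `max_iter` = 10 (flagged non-converged).

Missing phenotypes are removed listwise (with the matching kinship rows)
before any fit.

## Corrections

Bonferroni and Benjamini–Hochberg delegate to `statsmodels`; Storey
q-values use the single-λ estimator `π0 = min(1, #{p > λ}/((1−λ)m))` at
λ = 0.5 (a λ-grid average is available) and the π0-scaled step-up
`q_(i) = min_{j≥i} min(1, π0 m p_(j)/j)`, which reduces exactly to BH when
π0 = 1 and never exceeds it. Significance flags use 0.05 on adjusted
values; the fixed rule selects −log10(p) strictly greater than 3.5 on raw
p-values (the boundary 10⁻³·⁵ is excluded; the cutoff is configurable
because table-style "≥" usage also exists). Ties in p are ordered stably by
(p, marker index).

## Evaluation

Q-Q plots use the (i − 0.5)/m expected-quantile convention with a pointwise
95% band from exact Beta(i, m−i+1) order-statistic quantiles; the inflation
summary is the median observed 1-df χ² quantile over its null median
(0.4549). QTL recovery supports two matching rules, both reported because
"a significant SNP identifies a QTL" is inherently ambiguous: `exact` (the
causal marker itself is selected) and `ld` (any selected same-chromosome
marker within 1 Mb at r² ≥ 0.5); each QTL counts at most once, each
selected marker is assigned to at most one QTL (best r²), and unassigned
selections are false positives. The benchmark orchestrator runs the full
scenario × model × rule factorial, records per-cell failures without
aborting, and derives every stage seed from the master seed through
`SeedSequence`, so a configuration file plus one integer reproduces the
table digest exactly.

## Problem sizes

The test suite and acceptance checks run at deliberately desk-scale sizes
chosen to finish quickly while keeping every comparison meaningful:
heritability calibration at n = 500, m = 2,000 with 200 replicates; the
model-comparison table at n = 300, m = 5,000 over 10 replicate panels;
type-I calibration on 20,000 independent null markers; inflation ordering
and FarmCPU block behavior over 20 replicate panels each.

## Known limitations

- Desk-scale power: with H = 0.6 spread over 20 standard-normal effects at
  n = 300, only about a quarter of QTLs are individually detectable at
  −log10 p > 3.5, so absolute significant-marker counts are far below those
  of well-powered panels; qualitative orderings between models are the
  meaningful output. In particular, under mild confounding (Fst 0.1, two
  subpopulations) GLM's count can coincidentally land near the simulated
  QTL number, so "closest to Q" comparisons between models are not robust
  at this scale.
- The haplotype-pool LD model gives tunable block LD but not realistic
  decay tails; composite (dosage-level) r² is used throughout since phased
  haplotypes are never simulated.
- SUPER's theoretical power advantage over MLM materializes only when the
  all-marker kinship appreciably absorbs the tested QTL's signal; in small
  simulated panels the two are typically equivalent at the causal marker.
- Storey's PFDR uses the single-λ estimator; exact agreement with other
  PFDR implementations (different π0 estimators) is not expected.
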