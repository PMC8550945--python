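# Methods

## The model

`famvar` decomposes the phenotypic variance of a quantitative (or
dichotomized) trait measured in a family cohort into five named sources plus
residual noise:

    Y = Xb + u_G + u_K + u_F + u_C + u_S + eps

* **G** — additive genetic variance tagged by common genotyped SNPs,
  modelled through the genomic relationship matrix (GRM)
  `A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))`.
* **K** — additional genetic variance shared by close relatives (rare
  variants, untagged haplotypes).  Its matrix is the GRM with every
  off-diagonal entry below 0.025 set to zero, so only close-pedigree
  relationships survive; the diagonal keeps each individual's genomic
  self-relatedness.
* **F, C, S** — environments shared by nuclear families (parent–offspring,
  full-sibling and couple pairs set to 1), couples only, and full siblings
  only.  These are 0/1 indicator matrices with unit diagonal.
* **X** — fixed-effect covariates (intercept, age, sex; principal
  components and centre dummies are accepted as extra columns).

Variance components are estimated by restricted maximum likelihood and
reported as fractions of the (covariate-adjusted) phenotypic variance with
delta-method standard errors.

## The REML solver

`fit_reml` implements average-information (AI) REML:

* Starting values come from a Haseman–Elston-style least-squares fit of the
  fixed-effect-residualized cross-product matrix onto the component
  matrices — cheap, biased, but close enough that Newton steps converge in
  a handful of iterations.
* Each iteration solves the AI system on the *free* components only:
  a component pinned at the variance floor with an outward-pointing
  gradient is left on the boundary (active-set handling).  Steps that would
  reduce the restricted likelihood are halved, with a damped EM step as the
  fallback, so accepted iterations are monotone in the likelihood.
* Trial steps are evaluated with Cholesky solves only; the full projection
  matrix (needed for gradients, information and standard errors) is formed
  once per accepted iteration and once more at the optimum.
* Estimates are floored at `1e-6 × var(y)` and flagged when pinned
  (an unconstrained mode exists for likelihood-surface cross-checks).
  Convergence is declared when the log-likelihood changes by less than
  `tol` (default `1e-4`).  A near-singular information matrix (e.g. a
  component confounded with the residual) sets `identifiable=False` and
  falls back to a pseudo-inverse for the reported standard errors.

Wald tests are two-sided on the fraction scale; components pinned at the
floor report p = 1.  The LRT for one dropped component uses the 50:50
mixture of chi-square(0) and chi-square(1) appropriate for a variance on
the boundary (a plain chi-square option exists for sensitivity).  Backward
selection repeatedly removes the component that is non-significant in
*both* tests and has the largest Wald p, until every remaining component is
significant in at least one test; every decision is recorded in a trace.

For binary traits the model is fitted to 0/1 values on the observed scale
and fractions are transformed to the liability scale with
`h²_liab = h²_obs · K²(1−K)² / (P(1−P) z²)` (prevalence K, sample case
fraction P, z the standard-normal density at the threshold), which reduces
to `K(1−K)/z²` for population samples.

## The synthetic cohort

The generator is the package's ground-truth instrument; its defaults
emulate a family-based population cohort.

* **Pedigree.** Each of `n_families` starts as a founder couple with 1–3
  children.  A `mate_fraction` (default 0.5) share of those children are
  paired across families and have children of their own.  The resulting
  grandparent, avuncular and cousin pairs (relatedness 0.25 and 0.125 with
  no shared nuclear-family environment) are what make K separable from F:
  in a strictly two-generation design the model has an exact one-dimensional
  ridge (K can be traded against F and C without changing any modelled
  covariance), and the K estimate collapses to the boundary.
* **Genotypes.** Biallelic SNPs with allele frequencies uniform on the MAF
  range, founders drawn under Hardy–Weinberg equilibrium, descendants by
  Mendelian gene dropping (each parental allele transmitted with
  probability dosage/2).  SNPs are unlinked; positions are laid out on 22
  chromosomes so that distance-based windows are meaningful.  The default
  panels use 12,000–20,000 SNPs: large enough that GRM sampling noise
  (sd ≈ 1/√m) sits well below the 0.025 kinship cutoff, so the thresholded
  K matrix contains close relatives rather than noise — the same separation
  the cutoff achieves on a 500k-SNP array.
* **Phenotype.** `n_causal_snps` effects are drawn i.i.d. normal on
  standardized dosages (the infinitesimal assumption implicit in GREML).
  u_K is a pedigree-structured polygenic draw with covariance equal to the
  path-counting additive relationship matrix, factorized per extended
  family.  u_C and u_S are draws shared within couples and sibships.  u_F
  targets the F indicator; across marriage chains that indicator is
  indefinite, so each extended-family block is projected to its nearest
  positive-semidefinite matrix before sampling (within a two-generation
  family this reduces exactly to one shared draw).  Every component,
  including the residual, is rescaled to its exact target share of unit
  variance.  Small fixed effects of age (0.01 per year), sex (0.1) and
  centre (±0.05) are added on top; note that these widen the total
  liability beyond the unit-variance component sum by ~4%, which slightly
  attenuates recovered fractions for dichotomized traits (see Limitations).
* **Binary and ordinal traits.** The liability-threshold trait takes the
  top `prevalence` fraction of the realized liability as cases.  Ordinal
  encodings implement the interval coding used for cigarettes/day
  (0, less-than-daily, 1–4, 5–9, … 50+) and smoking age of onset
  (<5, 5–9, … 50+; unknown stays missing).
* **Cross-partner effects.** `partner_effect` (δ) adds δ × the partner's
  standardized SNP-genetic value to each coupled individual — an indirect
  genetic effect.  `assortment_rho` re-pairs founders by rank-matching a
  noisy copy of the pre-shared-environment phenotype (or of the genetic
  value, `assort_on="genetic"`), with the noise calibrated so the matched
  quantity correlates ≈ rho between partners; shared-environment terms are
  added only after matching, so phenotypic and genotypic assortment can be
  toggled independently.
* One integer seed drives a hierarchical stream (pedigree → genotypes →
  phenotype), so each stage is reproducible on its own.

What the generator does **not** emulate: linkage disequilibrium,
genotyping error and missingness patterns, population stratification,
X-chromosome transmission, age/cohort trends in substance use, or
behavioural convergence over relationship duration.  Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to those real-data features.

## Couples, scores and partner associations

* **Couple discovery.**  In pedigrees, couples are (father, mother)
  combinations sharing at least one child; individuals appearing in several
  combinations keep the pair with most shared children (ties by id) so each
  person is in at most one pair.  From household rosters, the filter
  cascade keeps households with exactly two recruited members who both
  report household size 2 and a husband/wife/partner relationship, then
  removes pairs with an age gap over 10 years or with matching father or
  mother ages (the cohabiting-sibling guard; it fires only when both values
  are non-missing).  Same-sex pairs are reported separately and used for
  phenotypic analyses only.
* **Polygenic scores.**  Per-SNP linear association on the
  covariate-residualized, standardized trait; greedy clumping (index SNP =
  smallest p, claiming same-chromosome SNPs within 250 kb at r² > 0.1); and
  clumping+thresholding scores on the grid 0.00005–0.5 in steps of 0.00005
  (10,000 thresholds, swept in one cumulative pass).  The selected
  threshold maximizes the incremental r² of the score over a
  covariate-only model (marginal r² is also reported).  Scores are
  residualized on the leading four principal components.  Effect alleles
  are aligned by explicit allele matching; strand-ambiguous SNPs are
  dropped.  Scoring refuses individuals who were in the GWAS training
  sample (id-set intersection).
* **Associations.**  Couple regressions z-scale both members so the
  reported beta is the Pearson correlation and r² = beta² (reported as a
  percentage).  Permutation tests shuffle member-b values across couples
  (10,000 Monte-Carlo resamplings by default; statistic = |correlation|;
  `p = (1 + hits)/(B + 1)`).  The single-SNP partner contrast stratifies
  reference-homozygotes by partner carrier status and compares group means
  with a Welch test.

## Problem sizes used in the checks

Desk-scale study conditions, chosen once as realistic emulations of a
family cohort while keeping a full run on one CPU in minutes:

* Full five-component recovery and the binary/liability analysis:
  1,200 families (~6,000 individuals across three generations),
  20,000 SNPs with 1,000 causal.
* Two-component backward-selection runs: 400 families of fixed size 4
  (~2,000 individuals), 12,000 SNPs.
* Null-calibration replicates: 36 families (~150 individuals), 500
  trait replicates on fixed matrices.
* Synthetic GWAS for score pipelines: 3,000 training founders and 1,000
  target couples on a 2,000-SNP panel.

## Known limitations

* The observed-to-liability transformation assumes the liability is
  standard normal at the threshold.  Because the generator adds covariate
  effects on top of the unit-variance components, the realized liability
  has variance ≈ 1.04, and recovered liability-scale fractions for
  dichotomized traits are attenuated by roughly that factor (≈ 3 points on
  a total of 80%); single-seed sampling noise at n ≈ 6,000 adds ±3–4
  points.  The quantitative-trait pipeline is unaffected.
* F, C and K are nearly collinear even with three generations; in full
  five-component fits a null F can absorb part of the couple or kinship
  variance in individual seeds.  Backward selection (the procedure used for
  the published component tables) resolves this by pruning unsupported
  components.
* The household algorithm assumes one roster record per individual and
  abstracts the relationship field to a single husband/wife/partner flag.
* Binary traits are analysed with a linear (observed-scale) model, not a
  threshold-model likelihood; this mirrors the workflow it re-implements.
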