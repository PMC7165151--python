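# Methods

This note documents the statistical procedures codsig implements, the
assumptions behind them, the synthetic-cohort generator used to test them,
and the numerical and design choices that were genuinely open.

## The analysis

Diffuse-type gastric cancer is clinically heterogeneous; the pipeline's
purpose is to derive, from a mixed-histology expression cohort, a gene
signature that splits diffuse-type tumors into an intestinal-like (INT)
subtype and a core diffuse-type (COD) subtype with different prognosis and
chemotherapy benefit, and then to exploit that split downstream.

### Signature derivation

Given a log2-scale genes × samples matrix and per-sample histology:

1. **Variance filter.** Genes whose sample standard deviation (denominator
   n − 1) strictly exceeds `sd_threshold` (default 0.9) are kept for
   clustering. Strict inequality is deliberate; lowering the threshold can
   only add genes (monotonicity is property-tested).
2. **Three-cluster discovery.** Samples are clustered agglomeratively on
   the filtered genes, by default with distance 1 − Pearson correlation
   and average linkage (both configurable; scipy's implementation with its
   deterministic merge ordering). The dendrogram is cut into exactly three
   flat clusters.
3. **Cluster labelling.** The cluster with the highest fraction of normal
   tissue samples is called N, the remaining cluster with the highest
   intestinal-type fraction INT, the remainder COD. A tie on one criterion
   is broken by the other; a tie on both is refused rather than guessed.
4. **Differential screen.** Restricted to diffuse-type samples (carrying
   their cluster membership from step 3), Welch's t test per gene gives
   list A (N vs INT clusters) and list B (INT vs COD clusters) at
   unadjusted P < `p_threshold` (default 0.001). No multiplicity
   correction is applied in this screen by design; a Benjamini–Hochberg
   column is available where screens are exported.
5. **Venn partition and signature.** only-A = A∖B (tumorigenesis-associated
   in this design), A∩B (shared), only-B = B∖A (progression into the core
   diffuse phenotype). The only-B genes form the signature, each with a
   direction sign: +1 if its mean in the COD-cluster diffuse samples
   exceeds its mean in the INT-cluster ones.

The worked arithmetic the derivation must reproduce exactly: lists of 737
and 2069 genes sharing 147 members decompose into 590 / 147 / 1922.

### Classification of new cohorts

Signature genes present in the new cohort (at least 25% of the signature
by default; missing genes are dropped, never imputed) are z-scored per
gene within the cohort, which cancels platform-wide location/scale shifts
between array and RNA-seq data. Two methods:

- **two_cluster** (default): hierarchical clustering of samples at k = 2
  on the z-scores, then orientation: the cluster with the higher mean
  direction-weighted signature score is COD. This mirrors the cohort-level
  procedure the signature was built for.
- **centroid**: each sample is labelled by the sign of its own mean
  direction-weighted z-score (COD if positive). This extends the procedure
  to single samples and is flagged as such in the output.

**Distance choice.** Classification clustering uses *euclidean* distance
on the z-scores, not 1 − Pearson. Correlation between two samples'
signature profiles is computed after centering each profile across genes,
so it is exactly invariant to a per-sample offset — but a signature whose
genes all move in one direction expresses the subtype *as* a per-sample
offset, which correlation then cannot see (labels degrade to chance; the
centroid method on the same data is perfect). The derivation-stage
clustering keeps 1 − Pearson, where multiple gene modules moving in
different directions give correlation real structure to work with.

### Survival analysis

- **Kaplan–Meier** product-limit estimator; censoring tied with an event
  time counts the censored subject in that event's risk set.
- **Log-rank test**: observed-minus-expected with the hypergeometric
  variance (including the (n−d)/(n−1) tie factor), χ² with 1 df.
- **Cox proportional hazards**: the partial likelihood is maximized by
  Newton–Raphson on internally standardized covariates, tolerance 1e-9 on
  the coefficient change, at most 100 iterations, with step-halving so the
  log-likelihood never decreases across accepted iterations. Efron
  tie-handling is the default (month-resolution survival data are heavily
  tied); Breslow is available. Wald CIs exp(β ± 1.96·SE) and Wald p-values
  are reported, matching the univariate/multivariate table convention.
  Complete-case handling for missing covariates, with dropped rows
  counted. Monotone likelihoods (complete separation) are detected and
  reported as errors naming the runaway covariate. The implementation is
  cross-checked in the tests against R's `survival::coxph` (frozen
  reference values, both tie methods, agreement to 1e-6) and lifelines.
- **Score-test anchor.** With Breslow ties and a single binary covariate
  the score test at β = 0 coincides with the log-rank statistic. The
  identity is exact only for untied event times: with d tied deaths the
  log-rank variance carries an (n−d)/(n−1) factor the Breslow information
  does not. Equivalence checks therefore use continuous simulated times,
  where agreement is at machine precision.
- **Variable selection**: backward elimination on Wald p at
  `retain_p` = 0.05, with the signature covariate optionally forced in;
  the dropped-variable path is recorded in the output.
- **Chemotherapy interaction**: a chemo-only Cox model per subtype stratum
  plus a pooled model with subtype, chemotherapy and their product term.
  Strata lacking both treatment arms are reported absent; the pooled model
  requires all four subtype × treatment cells.

### Mutation profiling

TMB is the raw per-sample count of nonsynonymous records (per-megabase
with a configurable exome size on request; nothing in the downstream
contrasts depends on the normalization choice). The INT/COD burden
contrast is Welch's t on log10(TMB + 1) by default, because mutation
counts are heavy-tailed; a raw-scale mode exists. The per-gene screen
builds a mutated/wild-type × INT/COD table per gene and applies the
two-sided Fisher exact test (point-probability rule, exact integer
arithmetic), unadjusted at α = 0.05, with a BH column alongside.
Molecular-subtype association (EBV/MSI/GS/CIN vs INT/COD) is a Pearson χ²
on the r × 2 table, with a warning when any expected count is below 5.

### Statistics conventions

- Welch (unequal-variance) t is used everywhere a two-sample t test is
  called for; pooling is never assumed. Zero variance in both groups gives
  p = 1 for equal means and p ≈ 0 for separated constants (a vanishing
  variance guard rather than a special case).
- Fisher's two-sided p sums all hypergeometric tables with point
  probability ≤ the observed table's. Probabilities are compared as exact
  integers (numerators over the common denominator C(n, c₁)), so ties are
  resolved exactly, with no floating-point tolerance. The odds ratio gets
  the Haldane 0.5 correction, flagged, when a cell is zero.
- "Biserial correlation" with a 0/1 dichotomy is implemented as
  point-biserial (≡ Pearson with the dummy coding); the latent-normal
  biserial coefficient is available behind a flag. The p-value always
  comes from the t-transform with n − 2 df.

## The synthetic-cohort generator

The generator produces cohorts with the latent structure the analysis
assumes, so that recovery is measurable against ground truth. It emulates:

- **Three latent expression groups.** Normals and intestinal-type tumors
  anchor the N and INT groups; diffuse tumors split N-like / INT-like /
  COD-like with configurable proportions (default 0.2 / 0.3 / 0.5, putting
  ~54 of 107 diffuse tumors in the COD group at the default cohort size of
  20 normal + 23 intestinal + 107 diffuse). A proliferation-like module
  (default 252 genes) is shifted up by `effect_size` in INT-group samples
  and an EMT-like module (default 397 genes) in COD-group samples, on a
  per-gene Gaussian baseline (mean 8, SD 1) with i.i.d. Gaussian noise
  (`noise_sd`, default 1.0). N-like diffuse tumors — tumors whose
  expression resembles normal stomach because of admixed normal cells —
  are a contamination mixture: 90% normal profile, 10% COD profile by
  default.
- **Subtype-dependent survival.** Event times are proportional-hazards
  Weibull (shape 1 = exponential by default): hazard = 0.02/month × 2.0
  for COD (`true_hr_cod`) × the per-subtype chemotherapy hazard ratio for
  treated patients (defaults 0.333 in COD, 0.576 in INT — a benefit
  concentrated in COD) × 1.02^(age−60) × 2.5^(stage−2). Censoring is an
  independent exponential (rate 0.01/month, ≈30% censoring at the default
  hazard) clipped at an optional administrative horizon. The
  `simulate_survival` entry point exposes the pure subtype/chemotherapy
  hazard block (no age/stage terms) for calibration studies.
- **Mutations.** Per diffuse sample, a negative-binomial background count
  (means 8 in INT-like, 2 in COD-like; dispersion 2, so TMB contrasts face
  realistic overdispersion) lands on uniformly drawn genes, plus
  designated marker loci drawn by per-subtype frequencies: a MUC16-like
  locus at 0.15/0.40 (INT/COD; overall rate ≈31% at the default mix), and
  PIK3CA-like (0.30/0.05) and ARID1A-like (0.25/0.04) loci enriched in
  INT. Marker loci live alongside the expression genes as their own
  identifiers.
- **Molecular subtypes** for diffuse tumors: categorical mixtures with
  MSI/EBV concentrated in the INT-like group and GS in the COD-like group.

All randomness flows through one seeded generator in a fixed, documented
draw order, so a config + seed is bit-reproducible. Effect sizes and noise
levels have no published estimates to anchor them; the defaults
(effect 1.0, noise 1.0; the recovery suites run at effect 2.0, noise 0.5)
are chosen for clean but non-trivial recovery and documented as arbitrary.

**What the generator does not emulate** — and hence what passing recovery
tests do *not* show about real data: read-count noise models, batch and
platform effects beyond a global shift, gene–gene correlation within and
between modules, signatures with mixed directions and heterogeneous
magnitudes, non-proportional hazards, informative censoring, and any
mechanistic link between mutations and expression. Recovery results are
statements about the pipeline's correctness under its own assumptions, not
about clinical performance.

## Numerical choices and degenerate inputs

- Cox covariates are standardized internally for conditioning and mapped
  back exactly; the partial likelihood is shift-invariant, so the centering
  does not change it.
- Constant covariates, empty groups, all-zero contingency tables, negative
  times, events without times, and zero-variance samples under correlation
  distance are rejected with named errors rather than propagated.
- A "constant gene" floor of 1e-10 relative to the data scale guards the
  classifier's z-scoring against floating-point residue in the SD of
  literally identical values.
- Duplicate gene rows collapse to the row with the highest mean expression
  by default (configurable to averaging); missing expression values are
  rejected unless per-gene median imputation is explicitly requested.
- AJCC substages (IIIa, IIIb, …) collapse to the main stage and enter Cox
  models as the ordinal 1–4.
- The expected input is a log2-scale, library-normalized expression
  matrix; the package does not attempt to infer or convert units.

## Problem sizes used by the checks

The recovery suites run at deliberately chosen sizes: signature recovery
on 20 cohorts of 150 samples × 2000 genes (modules 252/397); hazard-ratio
calibration on 1000 replicates of 400 patients (the coverage proportion's
Monte-Carlo error is then ~0.7 percentage points against a 93–97% band;
at 100 replicates a perfectly calibrated interval leaves that band about a
quarter of the time); chemotherapy-interaction recovery on 500 replicates
of 115 patients; null calibration on 10,000 genes (differential screen,
30/arm) and 2000 genes (mutation screen, 300/arm at carrier frequency
0.5). The mutation-screen size was fixed from an exact analysis of the
test's discreteness: the two-sided Fisher test's true size at α = 0.05 is
0.0431 at 150/arm and 0.0454 at 300/arm, so margins of 300/arm keep the
exact size within 3 binomial SDs of nominal, which is the calibration
band used. The end-to-end determinism check runs the full pipeline twice
at 150 samples × 5000 genes.

## Known limitations

- The derivation's clustering defaults (1 − Pearson, average linkage) are
  conventional for expression heatmaps, not uniquely correct; results
  record the parameters used.
- The per-gene mutation screen is unadjusted by design and will flag ~5%
  of null genes; the BH column is informational.
- The centroid classifier's threshold at 0 presumes the cohort used for
  z-scoring is roughly representative of both subtypes; a cohort of one
  subtype only will still be split.
- Fisher's exact test is conservative at small margins; its size
  approaches nominal α only as margins grow.
- No time-varying covariates, frailty terms, or competing risks in the
  survival suite; no batch correction beyond per-cohort z-scoring.
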