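# Methods

## The design in brief

`twinsens` implements a three-stage analysis of genetic *environmental
sensitivity* — the idea that some variants do not shift the mean of a
phenotype but amplify how strongly the environment acts on it
(differential susceptibility: "for better and for worse").

1. **Discovery (MZ discordance GWAS).** Monozygotic twins share their
   genome and family environment, so the absolute within-pair difference
   in a phenotype isolates non-shared environmental influence plus
   error.  A variant that scales the non-shared component (a
   variance-QTL) increases expected discordance in carriers; an ordinary
   mean-effect variant cancels in the pair difference.  Per SNP we
   regress covariate-residualized |y_A − y_B| on allele dosage with
   ancestry principal components.
2. **Polygenic environmental-sensitivity score.** Discovery βs are
   combined by clumping + thresholding: greedy p-value-ordered LD
   pruning (r² > 0.25 removed within ±200 kb), then, at each of eight
   p-value cutoffs (0.001 … 0.5), the β-weighted effect-allele count per
   individual, standardized.
3. **Moderation tests.** In an unrelated cohort the score is tested as a
   moderator of parenting (score × parenting interaction in OLS, with
   SES and PCs; ΔR² from nested fits on identical rows; rGE check by
   regressing the exposure on the score; 3×3 tertile tables).  In a
   clinical trial cohort the score is tested as a moderator of response
   to CBT of three intensities, in a full-ML linear mixed model of CSR
   change with subject and trial random intercepts, followed by per-arm
   fits, pairwise arm × score contrasts, remission tables,
   propensity-score matching and a comorbidity-adjusted sensitivity
   analysis.

## Generative model of the synthetic cohorts

All three cohorts share one variant panel with allele frequencies drawn
uniformly from `maf_range` and LD blocks produced by thresholding
equicorrelated latent Gaussians per haplotype (within-block latent
correlation `ld_rho`, default 0.7, block size 5, 50-kb spacing).

True sensitivity uses centred genotypes,

    s_i = s0 + Σ_k w_k (g_ik − 2 p_k),

so that `baseline_sensitivity` (s0) is the population-mean sensitivity
regardless of allele frequencies or locus count; with uncentred dosages
the mean of s would drift with MAF and the parameter would lose its
meaning.  Sensitivity loci carry no phenotypic main effect; main-effect
loci carry no sensitivity weight (a knob allows mixed architectures).

* **Twins**: y_ij = Σ β_G g_ik + c_i + s_i·E_ij + ε_ij with shared c_i
  per pair and per-member E, ε.  Discordance |y_A − y_B| is then
  half-normal with scale √2·|s_i|·ν (plus noise), which is what the
  discovery regression detects.
* **Validation**: exposure P ~ N(0,1) (+ optional rGE term), outcome
  y = main effects + s_i·P + noise.  Because s has no main-effect term,
  the interaction is a pure crossover.  The positive/negative parenting
  sub-scales are noisy components of the total, all oriented
  higher = more negative parenting.
* **Treatment**: CSR change at follow-up index t ∈ {0,1,2,3} is
  a + b·t + c·t² + arm effect + γ_arm·(s_i − s0) + diagnosis effect +
  subject and trial random intercepts + residual, then discretized by
  rounding and clamping CSR to 0..8 (the instrument is ordinal).
  Follow-ups are missing independently at `missing_rate`, except the
  post-treatment assessment, which is always observed.  The optional
  confounded-allocation mode draws arms from a logistic model of
  baseline severity and age only — severe/older children tend toward
  individual CBT (pre-match SMDs ≈ 0.5–0.8 on those drivers), the
  simplest mechanism that exercises propensity matching.

### Default parameters (the study conditions)

| parameter | default | why |
|---|---|---|
| n_pairs / n_unrelated / n_subjects | 1000 / 1400 / 900 | cohort scales of the target design |
| n_variants | 5000 | large enough for null calibration and clumping structure at desk scale |
| n_sensitivity_loci, w | 20, 0.4 | per-locus discordance z ≈ 3–4 at 1,000 pairs, so the aggregate score is estimable while single loci rarely reach genome-wide significance |
| s0, shared/nonshared/noise SD | 1.0, 0.7, 1.0, 1.0 | non-shared variance comparable to shared + error, typical for emotional symptoms |
| validation_noise_sd | 15.2 | calibrates the generative interaction share Var(s_c)/Var(y) to ≈ 0.5% of outcome variance (Var(s_c)=L·w²·E[2pq]≈1.17; solved analytically) |
| arm_moderation (γ) | (−0.5, 0, +0.5) | sensitivity helps under individual CBT, is neutral under group, hurts under brief parent-led |
| trajectory | (−2.0, −0.5, 0.08) | ≈ 2.8-point CSR drop by 12 months with a decelerating curve |
| subject_sd / trial_sd / residual_sd | 0.8 / 0.3 / 1.0 | ICC ≈ 0.35 at subject level, modest trial heterogeneity |
| missing_rate | 0.1 | realistic follow-up attrition |

A single phenotype-noise SD cannot simultaneously give the discovery
stage usable per-locus power and hold the validation interaction near
0.5% of variance, so the validation outcome has its own noise SD
(`validation_noise_sd`); this is the only place the two cohorts' noise
models differ.

### What the generator does not emulate

Realistic human LD maps and allele-frequency spectra; ordinal SDQ item
structure (the symptom composite is Gaussian); DZ twins; clinical
ascertainment; genotyping batch artifacts.  Passing tests therefore
demonstrate the statistical machinery and its calibration under the
assumed generative model, not performance on real array data.

## Estimators and numerical choices

* **HWE exact test**: conditional enumeration over heterozygote counts
  given allele counts, summing probabilities ≤ the observed one (no
  mid-p); symmetric in the homozygote counts; monomorphic variants get
  p = 1 and are instead removed by the MAF criterion.  QC presets:
  discovery (call rate ≥ 0.98, MAF ≥ 0.01, HWE p ≥ 1e−20) and treatment
  (≥ 0.99, ≥ 0.05, ≥ 1e−5).
* **PCA**: per-variant mean imputation of missing dosages, column
  standardization, truncated SVD (ARPACK) for small k.
* **Discordance GWAS**: two-stage by default (residualize on
  {intercept, age, sex, pair mean}, then per-SNP OLS on
  {intercept, dosage, PCs}); a joint single-stage model is available and
  agrees closely.  p-values from the t distribution with n−k−1 df;
  per-variant complete-case handling of missing dosages; monomorphic
  variants reported with a `no_variance` flag, never silently dropped.
  Suggestive/genome-wide flags at 1e−5 and 5e−8.
* **Clumping**: ±window semantics (total span 2×window_kb); ties on p
  broken by position then id; r² on unphased dosages (composite LD)
  with mean-imputed missing calls.
* **Scores**: allele alignment by matching effect/other alleles (a
  swapped orientation flips dosage g → 2−g; unresolvable mismatches are
  dropped with a warning); missing dosage imputed to 2×EAF; columns
  standardized with the mean/SD retained for back-transformation.
* **G×E**: interaction built from standardized score and exposure; ΔR²
  from nested fits on the identical (listwise-deleted) rows, equal to
  the squared semipartial correlation ×100; 95% CIs from the t
  distribution; tertiles by rank with stable tie-breaking.
* **Mixed model**: statsmodels MixedLM, full ML (not REML) so nested
  fixed-effect comparisons are valid; trial is the grouping random
  intercept with subject a variance component nested inside; time
  enters as the index 0..3 (months retained as an alternative column),
  linearly and quadratically; baseline CSR mean-centred.  Response is
  CSR_t − CSR_0, so positive coefficients mean poorer response.
  L-BFGS occasionally reports convergence at a spurious optimum with an
  absurd trial variance; the fit is rerun over a small optimizer ladder
  (powell, bfgs) whenever it is flagged non-converged or the trial
  variance exceeds the raw response variance, keeping the best
  log-likelihood.  Non-convergence is flagged on the result, never
  silently replaced.
* **Mixed-model variance explained**: defined as the increment in the
  marginal fixed-effect share, Var(Xβ̂)/(Var(Xβ̂)+σ²_subject+σ²_trial+
  σ²_residual), between nested fits on identical rows; this definition
  is recorded with the outputs.  With zero estimated random variances it
  reduces to the OLS ΔR².
* **Propensity matching**: pairwise logistic models per arm pair on the
  stated covariates (complete cases, dummy-coded), 1:1 greedy matching
  without replacement within a caliper of 0.2 SD of the logit.  The
  default partner metric is Mahalanobis distance on the standardized
  covariates within the caliper, which balances every covariate rather
  than only the propensity and dominates plain logit-nearest-neighbour
  at a few hundred subjects per arm; `metric="logit"` restores the
  plain rule.  Balance is reported as standardized mean differences
  before/after.  Note a hard floor: with ~150 matched pairs, covariates
  unrelated to allocation keep sampling-noise SMDs of roughly
  √(2/n) ≈ 0.12 per column under *any* without-replacement matcher, so
  "every SMD below 0.1" is only reachable at larger matched samples;
  what matching does deliver here is near-complete removal of the
  deliberate severity/age imbalance.
* **Remission**: post-treatment CSR < 4 (the caseness cut-off), by
  equal-count score tertiles and arm, with binomial SEs.

## Two-stage attenuation

The estimated score is a noisy proxy of true sensitivity, so any
downstream coefficient on the score is attenuated by
λ = Cov(score_z, s_c) relative to the same coefficient on the generative
moderator (classical measurement error).  Parameter-recovery checks
therefore compare the two-stage estimates against the truth-moderator
fit from the same replicate scaled by corr(score, s) — the quantity the
two-stage design can actually estimate — while direction/sign checks use
the raw estimates.  The interaction variance-share calibration (~0.5%)
is checked with the generative moderator itself; an estimated score with
corr ≈ 0.2–0.5 necessarily recovers only corr² of that share.

## Problem sizes used in validation

Simulation studies in the test suite run at reduced but statistically
meaningful sizes chosen as this package's own simulation design: null
calibrations use 2,000 independent variants × 1,000 pairs (discordance),
400 replicates × 300 individuals (G×E) and 120 replicates × 240 subjects
(arm × score); parameter recovery uses 20 replicate two-stage pipelines
at 1,000 pairs / 900 subjects / 1,200 variants and 100 replicate
validation cohorts at n = 1,400; bootstrap coverage uses 100 parametric
draws at 300 subjects.  All tolerance bands are binomial or Monte-Carlo
intervals recomputed at those replicate counts.

## Known limitations

* The ordinal CSR discretization slightly attenuates generative
  moderation effects relative to their continuous values; recovery
  checks use a same-replicate oracle so the comparison is unaffected.
* With few trials (the default is 5) the trial variance component is
  weakly identified; it is retained for fidelity to the design, not for
  interpretation.
* LD is exchangeable within fixed-size blocks — adequate for exercising
  clumping, far simpler than real haplotype structure.
* Strand-ambiguous (A/T, C/G) variants are unproblematic in simulation
  and are not specially handled; real-data use would need a strand
  check.
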