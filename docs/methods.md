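# Methods

## The question and the estimand

`multihet` tests whether multilocus heterozygosity (MLH) — the
per-individual count or proportion of heterozygous genotyped loci — is
associated with incident disease risk and with continuous risk-factor
levels in a nested case-control design. The primary estimand is the
odds ratio of disease per fixed number of additional heterozygous loci
(2000 for the all-autosomal and genic strata, 25 for nonsynonymous
SNPs; these units are roughly one standard deviation of each count on a
~700k-SNP array, and an `auto_unit` helper sets the unit to the
observed SD instead). Because risk-set sampling selects controls from
individuals still event-free at each case's event time, the odds ratio
estimates an incidence-rate ratio.

## Synthetic cohort generator

No individual-level cohort genotype data of this kind are public, so
the generator reproduces the *statistical structure* the analysis
relies on; all of its defaults are the study conditions.

* **Allele frequencies.** Ancestral frequencies are uniform on
  `[maf_low, maf_high]` = [0.01, 0.5]. With `n_subpops > 1`,
  subpopulation frequencies follow the Balding–Nichols model
  (Beta with mean *p* and variance Fst·*p*(1 − *p*)).
* **Inbreeding.** Per-individual *F* is Beta-distributed,
  re-parameterised by mean and SD and truncated to [0, 1). Defaults
  `f_mean = 0.002`, `f_sd = 0.008`: an outbred population where most
  individuals have *F* ≈ 0 and a tail carries higher autozygosity. The
  variance in *F* is deliberate — identity disequilibrium is the
  mechanism that makes MLH informative about inbreeding. With ~700k
  SNPs these defaults give a heterozygous-count SD of order 2×10³,
  matching the narrow spread such cohorts show.
* **Genotypes.** At a locus with subpopulation frequency *p*, an
  individual with inbreeding *F* is autozygous with probability *F*
  (homozygous: alt with probability *p*) and Hardy–Weinberg otherwise,
  so E[het] = (1 − *F*)·2*p*(1 − *p*). Loci are independent given *F*
  and subpopulation (no LD — a stated non-goal). Genotypes are masked
  missing completely at random at `missing_rate` (default 0.002; the
  cohorts' QC admits only samples with ≥97% call rate). The iid
  Bernoulli autozygosity and missingness masks are drawn sparsely
  (binomial count then Floyd's distinct-index sample), which is exactly
  equivalent to dense thinning and much faster at realistic rates.
* **Annotation.** SNPs sit at increasing positions (3–5 kb spacing) on
  ≥2 synthetic autosomes. Genes are laid out in alternating blocks
  sized so that after the flank rule (70 kb upstream / 20 kb
  downstream, strand-oriented) the genic stratum covers
  `genic_fraction` ≈ 81.2% of SNPs, and `nonsyn_fraction` ≈ 0.69% of
  SNPs (inside gene bodies only) are flagged nonsynonymous — the
  stratum proportions of a 692,794-SNP panel with 562,289 genic and
  4,760 nonsynonymous SNPs. Platform membership is "A,B" for all SNPs
  unless `platform_private_snps` plants single-platform SNPs.
* **Outcomes and matching.** Age is uniform on [45, 75] (banded in
  2-year strata for matching; the band width is a config knob since
  matching calipers are a design choice, not an inference), smoking is
  Bernoulli(0.25). Disease occurs in discrete time periods with a
  logistic hazard: logit(p) = logit(`baseline_prevalence`) +
  `beta_per_2000`·(het − mean het)/2000 (+ optional per-subpopulation
  shifts, the confounding lever). Discrete-time geometric event times
  are the simplest model supporting risk-set-sampling semantics. Each
  case is matched, in event-time order, to `controls_per_case` = 2
  controls still event-free at that time from the same age band and
  smoking stratum; controls are used at most once; a control who later
  becomes a case is kept once, as a case; sets with no eligible control
  are dropped and logged.
* **Biomarkers.** Thirteen traits named after a cardiovascular panel
  (lipids, inflammatory markers, adhesion molecules, adiponectin, BMI),
  each `gamma_per_2000`·het/2000 + 0.05·(age − 60) + 0.3·smoking +
  N(0, 1). Gamma defaults to 0 — the null that the biomarker screen is
  calibrated against. `biomarker_missing_fraction` masks an exact-size
  random subset, mimicking traits measured only in an initial subset.

Identical `SimulationConfig` (including seed) gives bit-identical
output; the RNG is consumed in a fixed order with chunk sizes that
depend only on the problem dimensions.

What the generator does **not** emulate: linkage disequilibrium,
allele-frequency spectra skewed by array ascertainment beyond a uniform
MAF band, relatedness, batch effects, genotyping error, and
continuous-time hazards. Passing tests therefore demonstrate the
pipeline's statistical correctness under the assumed structure, not
robustness to artefacts real arrays can show.

## Quality control

Fixed, logged order: sample call rate → sex consistency → platform
intersection → Hardy–Weinberg in controls; the first rule to fire is
the one recorded reason, and re-running QC on filtered output is a
no-op. Call rate uses strict `< 0.97` (a sample exactly at the
threshold is kept). The sex check infers sex from the X-heterozygosity
rate (≤ 0.02 male, ≥ 0.20 female, otherwise indeterminate-and-retained)
and is skipped with a warning below 50 X SNPs; the thresholds are
explicit config because the underlying rule ("sex mismatch") names no
numbers. SNP-level call-rate filtering is *not* applied by default
(only a sample call-rate rule is part of the design), and HWE filtering
pools all controls by default (a per-sex option exists; cohorts here
are single-sex anyway).

The HWE test is the exact conditional test: given allele counts
(n_A, n_a), the heterozygote count *h* has probability ∝
2^h · n!/(n_AA! h! n_aa!); the two-sided p-value sums all
configurations no more probable than the observed one (the standard
convention; mid-p is available behind a flag, off by default).
Implementation uses log-gamma weights with per-allele-count
memoisation; the test suite checks it against an exact-integer
enumeration oracle for every table with ≤ 50 individuals.

## Heterozygosity strata

Genic membership is interval membership in gene bodies extended 70 kb
upstream and 20 kb downstream oriented by strand, clamped at position
1, with overlapping intervals merged and each SNP counted once (set
semantics — whether a multi-gene SNP should count once or per gene is
an interpretation; set semantics is the one implemented). The
asymmetric flank pair is read as upstream/downstream. Counts use each
individual's own non-missing denominator; count and proportion are both
first-class and give identical z-statistics when missingness is
uniform. Effects fitted per SNP rescale linearly to any reporting unit
(SE and CI endpoints transform identically), and fitting the
pre-scaled exposure reproduces the rescaled fit to numerical tolerance.

## Stratification adjustment

Genotypes are centred at 2p̂ and scaled by √(2p̂(1 − p̂)) (monomorphic
SNPs dropped, missing values mean-imputed); the top k = 3 eigenvectors
of the individual covariance are the ancestry covariates. PCA runs on
every 10th SNP by default — stratification signal is dense, and the
thinning factor is configurable. The sign convention (largest-magnitude
coordinate positive) makes output deterministic. Ancestry outliers
(> 6 SD on any component) are flagged but excluded only on request,
standing in for reference-panel ancestry restriction, which needs
external data and is out of scope.

## Association models

Case status is fit by unconditional maximum-likelihood logistic
regression (IRLS) with matching factors as covariates rather than by
conditioning on matched sets — the design choice that also dictates
that subgroup filters (e.g. age < 65 at blood draw, strict) simply drop
individuals without regard to set integrity. Wald CIs and p-values are
reported; separation or non-convergence flags the result instead of
silently emitting numbers. Biomarker models add case-control status as
a covariate; "mixed models" is interpreted as offering both a
fixed-effects-only form and a per-matched-set random intercept (REML),
since the random-effects structure is ambiguous in prose. Summary
tables report case/control means ± SD with a two-sided Welch t-test for
the mean difference (the test used for the table is a configuration
choice and is named in the output). No multiple-testing correction is
applied across the strata × traits grid by default — a single global
hypothesis is being tested at conventional significance — and
Bonferroni is available behind a flag.

## Replicated calibration studies and problem sizes

The studies in `multihet.studies` re-run the generator and modelling
path end to end. Sizes were chosen so the full suite runs in minutes
on one CPU; the properties under test do not depend on the scaled
dimension:

* **Null calibration / effect recovery** — cohorts of 2600 individuals
  with per-period hazard 0.022 over 8 periods (≈ 435 cases, 1:2
  matched), 20,000 SNPs per replicate; 200 null replicates (CI
  coverage, type-I error) and 100 planted-effect replicates
  (log-OR ln 1.25 per 2000 loci). The SNP count only sets the SD of the
  exposure; coverage and type-I error are scale-free. QC is skipped
  inside replicates (no missingness or violations are planted, so it
  is a no-op exercised separately).
* **Stratification confounding** — two subpopulations at Fst = 0.15
  whose disease risk differs by 1.5 log-odds and no heterozygosity
  effect; 1500 individuals × 2000 SNPs × 200 replicates. Drifted
  frequencies shift each subpopulation's mean heterozygosity, so the
  unadjusted model inflates type-I error well above 0.10 while the
  3-eigenvector-adjusted model returns it to ≈ 0.05. The regime was
  sized by an omitted-variable-bias calculation: the spurious-slope SD
  across replicates must exceed the per-replicate SE for inflation to
  be visible.
* **Biomarker null grid** — 20 replicates of 900-individual ×
  15,000-SNP cohorts, 13 traits × 3 strata with all slopes zero; the
  significant fraction at α = 0.05 sits at chance level.
* **Heterozygosity–inbreeding identity** — one 500 × 50,000 simulation
  with `f_mean = f_sd = 0.05`: the mean het proportion matches
  (1 − E[F])·mean(2pq) within Monte-Carlo error and the regression of
  proportion on true *F* recovers slope −mean(2pq).

A small planted-violation QC panel (20 individuals × 200 SNPs) checks
filter bookkeeping exactly; the HWE violation is constructed so that
its exact p-value (8.6×10⁻⁵ with 14 controls, all homozygous, alleles
split 7/7) falls just below the 10⁻⁴ threshold, and the planted
low-call-rate and sex-mismatch individuals sit among the cases so the
control tally is undisturbed.

## Numerical notes and edge cases

* Genotype codes count non-reference alleles; every statistic depends
  only on `code == 1`, so allele-polarity flips are no-ops (tested).
* Monomorphic sites have HWE p = 1 (a single attainable
  configuration); an all-zero count table is an error.
* The exact-test tail comparison uses a 1 + 10⁻¹² relative slack so
  ties at the observed probability are included despite floating-point
  rounding.
* The discrete-time hazard at p = 0 or 1 maps to "never" / "first
  period" event times rather than NaNs.
* PCA eigen-decomposition uses LAPACK's subset solver on the
  individual-covariance matrix (deterministic; no randomized SVD).
* The per-2000-loci odds ratio from the discrete-time design shows a
  mild (~10–15%) away-from-null deviation at implausibly large planted
  effects (|log OR| ≈ 2 per 2000), the expected gap between a
  per-period logistic hazard coefficient and the cumulative-follow-up
  odds ratio; at realistic effect sizes it is negligible relative to
  sampling error.

## Known limitations

Conditional logistic regression, Cox models, per-SNP GWAS, runs of
homozygosity, g2-type identity-disequilibrium estimators, imputed
dosages, BGEN, and reference-panel ancestry projection are out of
scope. The simulator's independence assumptions mean LD-sensitive
behaviours (e.g. PCA SNP-thinning trade-offs on real data) are not
characterised here.
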