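# Methods

## Scientific setting

The package estimates the causal effect of a maternal exposure (adiposity
traits, in SD units) on offspring birthweight from GWAS summary statistics,
in a two-sample Mendelian randomisation design. The central confounder this
design must handle is the transmitted genotype: a mother shares half her
alleles with her child, so a "maternal" SNP–birthweight association in a
marginal GWAS partly reflects a direct fetal effect and vice versa. All
downstream estimators therefore consume **maternal** genetic effects that
have been freed of fetal effects, either by the summary-level weighted
linear model (WLM) or by conditional regression in genotyped mother–child
duos.

## Maternal/fetal decomposition (WLM)

With the 0.5 mother–child genotype correlation, the marginal expectations
per SNP are

    E[beta_own] = beta_fetal    + 0.5 beta_maternal
    E[beta_off] = beta_maternal + 0.5 beta_fetal

and the decomposition inverts the 2×2 system:

    beta_maternal = (4 beta_off − 2 beta_own) / 3
    var_maternal  = (16 se_off² + 4 se_own² − 16 cov_own_off) / 9

(fetal symmetric with roles swapped). `cov_own_off` defaults to 0, which is
exact when the own-birthweight and offspring-birthweight GWAS samples do not
overlap; for overlapping samples the covariance must be supplied (an
overlapping-sample covariance near its Cauchy–Schwarz bound can make the
decomposed variance collapse, which is refused as degenerate). The
decomposition is per SNP, vectorised over tables, with no shrinkage.

The individual-level counterpart regresses offspring outcome on
[intercept, maternal dosage, child dosage, covariates]; on a shared
synthetic population the two routes' per-SNP maternal estimates correlate
>0.999, which is the package's internal consistency check between its
summary-level and individual-level machinery.

## Harmonisation

Outcome associations are aligned to the exposure table's alleles: identical
allele pairs are kept; swapped pairs negate the outcome beta and reflect its
EAF; pairs matching only after strand complementation (A↔T, C↔G) are
complemented first; anything else is excluded as an allele mismatch. After
matching, each record is oriented to the **exposure-increasing** allele
(negating both betas and relabelling alleles where the exposure beta is
negative), so `beta_x ≥ 0` everywhere downstream — MR-Egger requires this
orientation. Palindromic (A/T, G/C) variants carry no strand information in
their labels; they are resolved by allele-frequency agreement and excluded
when either EAF is missing or within `palindromic_eaf_window` (default
0.08) of 0.5. The window is a config parameter because published analyses
rarely state their rule; 0.08 excludes variants whose minor allele cannot be
identified reliably across typical cohort frequency noise. Indels and
multi-allelic records are rejected at read time. One harmonised record per
exposure SNP is always emitted (matched + excluded conserves counts), which
the pipeline's audit block relies on.

## Estimators and numerical conventions

* **Wald ratio**: theta = beta_y/beta_x, se = se_y/|beta_x| (first order;
  exposure-side uncertainty ignored, appropriate for strong instruments).
* **IVW**: fixed-effect pool of ratios; algebraically identical (to ~1e-14
  relative) to weighted least squares of beta_y on beta_x through the
  origin with weights 1/se_y². The multiplicative-random-effects variant
  keeps the point estimate and inflates the SE by sqrt(max(1, Q/df)).
* **Cochran's Q / I²**: Q = Σ w_j (theta_j − beta_pool)²; I² = max(0,
  (Q−df)/Q)·100; p from the chi-square upper tail.
* **MR-Egger**: WLS of beta_y on beta_x with intercept, weights 1/se_y²;
  SEs use multiplicative overdispersion floored at 1 (the floor prevents
  anti-conservative SEs when the data are under-dispersed). Two-sided
  normal p-values throughout; a t-option is deliberately not the default.
* **Weighted median**: ratios ordered, cumulative standardised weights
  p_j = (Σ_{i≤j} w_i − w_j/2)/Σw, linear interpolation at p = 0.5; SE from
  a parametric bootstrap (default 1000 seeded draws of beta_x and beta_y
  from normals at their SEs; below 100 draws a warning is raised).
* **Radial MR**: regress beta_y/se_y on beta_x/se_y (through the origin for
  the IVW variant, with intercept for the Egger variant); each squared
  residual is that SNP's contribution to the global Q (the IVW-variant
  contributions sum exactly to Cochran's Q with first-order weights) and is
  referred to chi-square(1); default flagging alpha 0.05, with
  Bonferroni-per-SNP alpha used in the calibration tests.
* **Multivariable MR**: WLS of beta_y on K exposure-beta columns without
  intercept, weights 1/se_y², overdispersion as in Egger; rank deficiency
  is refused with the offending columns named. K = 1 is permitted and
  reduces exactly to IVW.
* Perfect-fit GWAS regressions (e.g. a constant trait) receive an SE floor
  of 1e-12 rather than zero, keeping downstream weights finite.

Estimates are produced in SD-outcome units and rescaled linearly to natural
units; the defaults encode 1 SD birthweight ≈ 484 g, 1 SD body fat
percentage = 6.5%, 1 SD BMI = 4 kg/m².

## Synthetic data generator

The generator exists so every estimator is testable against known truth.
Per SNP j with frequency f_j: maternal dosage is the sum of two Bernoulli(f)
alleles; the child receives one allele drawn uniformly from the mother's two
plus an independent paternal Bernoulli(f) allele (random mating), giving the
0.5 mother–child dosage correlation in expectation and Hardy–Weinberg
dosage variance 2f(1−f). The maternal exposure is

    X = Σ_j beta_j G_mother,j + e,   Var(X) = 1,

with per-allele betas drawn as heavy-right-tailed shapes (0.3 + Exp(1)) with
random signs, rescaled so the score explains exactly `exposure_h2_target`;
user-supplied betas are used as-is and refused if their implied score
variance reaches the unit exposure variance. A scalar mediator (the
fasting-glucose role) is M = X + Γ·G_mother + noise, where the optional
per-SNP direct effects Γ exist because multivariable MR is unidentified
when the mediator's genetic column is proportional to the exposure's. The
offspring outcome (SD units) is

    Y = theta · [(1−m) X + m M] + beta_fetal·G_child + alpha·G_pleio + e_Y,

with mediation fraction m, so the total causal effect of one SD of exposure
is exactly `theta_maternal` regardless of m. The outcome residual variance
is set to one minus the realised systematic variance (floored at 0.05), an
approximate standardisation that keeps Y near unit variance without
rescaling the effects.

**Pleiotropy semantics.** Directional pleiotropy is defined *relative to
the exposure-increasing allele*: each affected SNP receives +`magnitude` SD
per copy of the allele that raises the exposure. This matters because
harmonisation re-orients every SNP to that allele; a fixed per-allele sign
would be randomised by orientation and become balanced pleiotropy.
Balanced mode assigns ±magnitude with random signs; `via_fetal` routes the
effect through the child's genotype to stress the decomposition.

**Two-sample structure.** `make_two_sample_dataset` draws two populations
from independent seeded substreams (exposure and mediator GWAS from
population 1; outcome GWAS from population 2) and splits population 2 into
disjoint halves for the own-birthweight and offspring-birthweight GWAS.
The split makes the own/offspring sampling covariance exactly zero — the
condition under which the decomposition's default `cov_own_off = 0` is
correct. Running both marginal GWAS on the same duos would induce a
covariance ≈ 0.5·se_own·se_off and overstate WLM SEs by ~30%, visibly
over-covering the IVW confidence interval. Outcome allele orientations are
randomly scrambled by default so harmonisation is always exercised end to
end. All draws flow through `numpy` Generators seeded from (seed, stream)
pairs, so outputs are bit-reproducible.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| n_snps | 14 | size of a small adiposity instrument set |
| n_individuals | 20,000 per population | large-cohort scale that runs in milliseconds |
| exposure_h2_target | 0.02 | a few percent of trait variance from a small instrument set; per-SNP F ≈ 28 at n = 20k |
| theta_maternal | −0.2 SD/SD (≈ −97 g) | adiposity-scale effect on birthweight |
| mediation_fraction | 0.5 | illustrative; no published calibration exists |
| mediator_noise_sd | 1.0 | mediator roughly half genetic-plus-exposure, half noise |
| pleiotropy | none | violations are opt-in per scenario |

The pleiotropy stress scenario used in the calibration tests (50 SNPs, 30%
directional at 0.1 SD/allele, h2 = 0.05, exposure sample 50,000) keeps the
per-SNP F-statistic near 50. Instrument strength is not a free dial here:
MR instruments are genome-wide-significant by construction, and letting
per-SNP F drop to ~8 (as a naive 50-SNP scaling of the defaults would)
breaks the exposure-increasing orientation for the weakest SNPs — observed
sign flips convert directional pleiotropy into partially balanced
pleiotropy and regression dilution attenuates the Egger fit, i.e. the
scenario would contradict the assumptions the estimator is defined under.
The 0.1 SD/allele magnitude makes the invalid pathway roughly an order of
magnitude stronger than the exposure-mediated one — the deliberate-gross
regime in which pleiotropy diagnostics are meant to trigger, with predicted
Egger-intercept power ≈ 65% at these settings (observed ≈ 62–63%).

### What the generator does *not* emulate

No linkage disequilibrium between instruments, no population
stratification or assortative mating, no dynastic pathways beyond the
explicit maternal and fetal channels, a single scalar mediator, no
case-control ascertainment, and no sample overlap between the two samples.
Passing calibration tests therefore demonstrate correctness of the
estimators under the stated sampling model, not robustness to these
real-data complications.

## Problem sizes in the test and acceptance runs

The calibration tests use 1000 replicates for IVW coverage, 500 for the
pleiotropy and radial-outlier rates, one 20,000-pair population for the
WLM-vs-conditional comparison, and 100/1000 random instances for the
IVW/WLS and WLM round-trip identities — sizes at which the binomial noise
of the measured rates is well inside the asserted bands. The acceptance
script repeats the same computations at 200–300 replicates, which keeps its
runtime near a minute while leaving its rates within ~2 percentage points
of the test-suite values.

## Known limitations

* Wald-ratio SEs are first order; with weak instruments both the SE and
  the point estimate (weak-instrument bias toward the confounded
  association) degrade, and the package does not implement Steiger
  filtering, MR-PRESSO, or correlated-instrument (LD-aware) methods.
* The WLM is the linear approximation to the full structural-equation
  decomposition; paternal effects and X-chromosome inheritance are out of
  scope.
* The weighted median's parametric bootstrap assumes normal sampling of the
  summary statistics; its known finite-sample bias under heavy per-SNP
  noise is documented behaviour, not corrected.
* Logistic score–covariate checks report log-odds slopes and rely on
  statsmodels' MLE; separation in tiny samples is not specially handled.
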