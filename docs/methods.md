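# Methods

## Score model

The polygenic risk score is the additive weighted allele count
PRS = Σᵢ βᵢxᵢ, where xᵢ ∈ {0, 1, 2} is the effect-allele dosage at panel
SNP i and βᵢ its per-allele log odds ratio from external GWAS summary
statistics. The model assumes additivity on the log-odds scale both
across alleles at a locus and across loci; no dominance, interaction, or
LD-aware shrinkage is modelled, and none is intended — the weights panel
is a user input and the score is exactly its weighted dosage sum.

Raw scores are standardized to the control series: std = (raw − μ̂c)/σ̂c
with μ̂c, σ̂c the control mean and SD. The SD uses the n−1 denominator,
matching the default of mainstream statistical software. Standardization
parameters are data-dependent quantities, recomputed from whatever
control series is supplied, never constants of the package.

Missing dosages are imputed by default with the SNP's mean non-missing
dosage across all individuals (`missing_policy="impute_mean_dosage"`);
a strict `"error"` policy is available for pipelines that prefer to fail
on missingness. With no missing data the two policies coincide exactly.

## SNP-level QC

* **Strand-ambiguous removal.** SNPs whose allele pair is {A,T} or {C,G}
  are indistinguishable between DNA strands and are removed first. This
  filter is idempotent.
* **Orientation resolution.** VCF REF/ALT must equal the weight record's
  allele pair; when the effect allele is REF, dosage = 2 − ALT count.
  A REF/ALT pair matching the *complement* of the weight alleles raises
  a hard error rather than being silently strand-flipped: with
  palindromic SNPs already removed a complement match almost certainly
  indicates a strand annotation problem, and a silent flip would corrupt
  dosages undetectably.
* **Read-depth filter.** A genotype whose per-sample DP is below 30
  (configurable) is set missing; absent DP means no depth filtering.
* **LD pruning.** Pairwise r² is the squared Pearson correlation of
  dosages over complete pairs (composite LD — phase is unavailable in
  unphased VCFs). SNPs are scanned in (chromosome, position) order and
  whenever a retained pair has r² > 0.45 the member with the smaller |β|
  is dropped (ties: the later in order), so the retained panel never
  contains a violating pair. Keeping the larger-|β| SNP retains the more
  informative marker; the threshold is configurable. Pairs with
  undefined r² (constant dosage columns) never force a drop.

## Risk models

* **Deciles.** Cutpoints are the 10%…90% empirical quantiles of the
  reference distribution under linear interpolation between order
  statistics (the "type 7" rule — the default of both numpy and R).
  Bins are left-open/right-closed: a score exactly at a cutpoint falls
  in the lower decile. This tie-break is arbitrary but deterministic and
  documented; any strictly monotone transform of scores and cutpoints
  leaves assignments unchanged. The melanoma analysis merges deciles 5
  and 6 into one reference group; the merge is a label-mapping step, so
  the MPM analysis (reference = decile 1, no merge) reuses the same
  machinery.
* **Odds ratios.** Crude ORs come equivalently from the 2×2
  cross-product ad/bc or from a logistic fit with group indicators (the
  saturated-model identity; the package tests both routes against each
  other to 1e-6). Adjusted models add age at sampling as a continuous
  covariate and sex as a binary indicator. Zero-cell ORs raise by
  default; a Haldane 0.5 continuity correction exists behind an explicit
  flag for exploratory use only.
* **Confidence intervals.** Wald throughout, exp(log OR ± z·SE) with
  z = 1.959964 at 95%, SE from √(1/a+1/b+1/c+1/d) or from the inverse
  observed information of the fit. No profile-likelihood intervals, and
  no multiple-testing adjustment anywhere.
* **Logistic fitting** is Newton-type IRLS (via statsmodels) with at
  most 50 iterations and a 1e-8 gradient tolerance. Diverging
  coefficients (|β| > 30), non-finite covariance, or a statsmodels
  separation exception raise `SeparationError`; a singular design raises
  `ValueError`.

## Discrimination

AUC is the Mann–Whitney estimator with the 1/2 tie convention, computed
from midranks in O(n log n). Variances and the covariance of two AUCs
measured on the same individuals come from DeLong placement values; the
paired test statistic is z = (AUC₂ − AUC₁)/√(var₁ + var₂ − 2cov) with a
two-sided normal p. When the two score vectors rank individuals
identically the variance of the difference is exactly zero and the
comparison returns z = 0, p = 1 by convention. Nested-model comparisons
use in-sample fitted probabilities — no cross-validation — which mirrors
the within-cohort comparisons this analysis is designed for and
therefore carries the usual optimism of apparent AUCs. Both the
decile-categorized and continuous-score PRS models can be compared.

## Group tests

Kruskal–Wallis with midranks and tie correction, p from the chi-square
approximation with g−1 df. Group sizes in the intended use (≥ 20 per
stratum) are comfortably asymptotic; the test suite checks the
approximation against a 50,000-draw permutation null at small n.
Stratified summaries report mean (SD) and median (Q1, Q3) at 3 decimals
using the same type-7 quantile rule as the decile cutpoints, exclude
missing phenotype values pairwise per comparison, and omit (with a
warning) strata emptied by the exclusion. All-identical values raise,
since H is undefined after tie correction.

## Synthetic cohorts

The generator emulates the study design the analysis assumes, not any
real cohort's joint distribution.

* **Genotypes**: dosage ~ Binomial(2, pⱼ) under HWE, SNPs independent;
  allele frequencies Uniform(0.05, 0.5). An optional block-copy mode
  (each SNP in a block copies the block head's dosage with probability
  0.9) induces LD solely to exercise pruning.
* **Panel**: 57 SNPs by default; β ~ Normal(0.047, 0.13). These moments
  target, in expectation, a raw-score scale typical of a GWAS-derived
  melanoma panel of this size (control mean ≈ 1.5, SD ≈ 0.6); individual
  seeded panels scatter around that expectation.
* **Case status** is retrospective (case-control): candidates are drawn
  from the population model and assigned case status with
  logit(p) = α + ln(per-SD OR)·z + β_age(age − μ_age) + β_male·male,
  where z is the score in population-SD units; α is tuned by bisection
  on a dedicated candidate pool of 8,000 so the expected case fraction
  matches the requested quota ratio, then sampling continues until
  exactly n_cases and n_controls accumulate. ORs, not absolute risks,
  are the estimands throughout, which retrospective sampling preserves.
  Defaults: per-SD OR 1.5, 270 cases, 296 controls.
* **Covariates**: age ~ Normal(48.5, 14); P(male) = 0.65. The default
  age effect (+0.08/year) and male effect (−1.26) reproduce the marginal
  gaps of a case series recruited in clinic against blood-donor controls
  — cases older (≈57 vs ≈41) and less often male (≈43% vs ≈72%). The
  negative "male effect" encodes the donor series' sex imbalance, not
  melanoma biology.
* **Melanoma counts**: every case starts at 1; each additional primary
  occurs sequentially with log-odds 0.62 + gradient·z (default gradient
  ln 1.41 per score SD), capped at 4 = "4 or more"; failing one step
  ends the sequence. This yields ≈65% multiple-primary cases at z = 0
  and a rising mean score across count categories.
* **Phenotypes** (cases only, as in a clinic questionnaire): binary
  traits drawn with P = sigmoid(logit(base rate) + assoc·z); hair color
  is a 3-level multinomial logit with blonde and red both score-linked.
  Default base rates and score associations give light-pigmentation
  phenotypes higher mean scores. Missingness is injected per variable at
  clinic-like rates (12.6–20.7%). Age at diagnosis is Normal(49.6 −
  4.8·z, 14.9), younger with higher score.
* **Reproducibility**: one integer seed, split into fixed named
  substreams (panel, frequencies, genotypes, status, phenotypes, vcf),
  so adding a phenotype draw never perturbs genotype draws; written
  files are byte-identical for the same seed.

What passing tests on synthetic data do **not** show: robustness to
population structure, realistic allele-frequency spectra, genuine LD
patterns, informative missingness, or covariate-score confounding —
none of which the generator produces.

## Numerical and design notes

* Scores are carried at full double precision; rounding (2 d.p. for
  ORs, 3 d.p. for summaries) happens only in report formatting.
* Recovery simulations of the per-SD OR zero the age/sex effects: a
  univariate marginal fit under strong omitted covariates estimates an
  attenuated marginal OR (non-collapsibility), which is not the
  conditional effect being recovered. With covariates in the generating
  model, the adjusted fit is the appropriate estimator.
* The per-SD OR for the MPM outcome is crude by default, with an
  adjustment hook, since the corresponding published analyses are
  univariate.
* Problem sizes used by the test suite and the acceptance script
  (replicate counts of 100–200 at n = 2,000, permutation nulls of
  50,000 draws, bootstrap oracles of 10,000 draws) were chosen to keep
  Monte-Carlo error well below the asserted margins while remaining
  quick on a single CPU.

## Known limitations

Biallelic SNPs only — indels and multi-allelic sites are rejected, not
decomposed. No imputation from reference panels; a panel SNP absent from
the VCF is simply missing. No absolute-risk calibration, survival
modelling, or optimism-corrected/external validation of AUCs. Wald CIs
degrade with very sparse cells; the package raises rather than
continuity-correct by default.
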