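# Methods

`directmr` implements two-sample Mendelian randomization (MR) with GWAS
summary statistics, aimed at the study design that motivated it: separating
the **direct** effect of an early-life exposure (childhood body size, a
three-category "thinner / about average / plumper" variable) from the effect
of a correlated later-life exposure (adult body size, categorised the same
way) on a binary disease outcome (colorectal cancer, overall and by
anatomical subsite and sex). This note records the statistical model, the
estimators, the numerical conventions, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the design
was genuinely open.

## Model and notation

For SNP *j*, let γ̂₁ⱼ (SE σ₁ⱼ) and γ̂₂ⱼ (SE σ₂ⱼ) be its estimated
per-allele associations with exposures 1 and 2 in per-category units, and
Γ̂ⱼ (SE σ_Yⱼ) its estimated log-odds association with the outcome, all
referring to the same effect allele after harmonization. The standard
instrumental-variable assumptions (relevance, exchangeability, exclusion
restriction) give, per SNP, Γⱼ = θ·γ₁ⱼ in the univariable case and
Γⱼ = θ₁·γ₁ⱼ + θ₂·γ₂ⱼ in the two-exposure case, where θ (total effect) and
θ₁, θ₂ (direct effects) are log odds ratios per category change. All
reported CIs are θ ± z₀.₉₇₅·SE with normal-distribution p-values — the
large-L summary-data convention; odds ratios are exp(θ).

## Estimators

**Wald ratio** — θ̂ⱼ = Γ̂ⱼ/γ̂₁ⱼ with first-order SE σ_Yⱼ/|γ̂₁ⱼ|.

**IVW** — weighted regression of Γ̂ on γ̂₁ through the origin with weights
wⱼ = 1/σ_Yⱼ²; equivalently the inverse-variance-weighted mean of Wald
ratios. Cochran's Q = Σ wⱼ(Γ̂ⱼ − θ̂γ̂₁ⱼ)² on L−1 df diagnoses
heterogeneity. In multiplicative random-effects mode the fixed-effect SE is
inflated by max(1, √(Q/(L−1))); `auto` mode (the default in the pipeline)
applies the inflation when Q's p-value is below 0.05. Point estimates are
identical in all modes; the 0.05 switching threshold is a package choice —
the switch rule itself is standard, its threshold rarely stated.

**MR-Egger** — the same weighted regression with a free intercept, records
first oriented so every γ̂₁ⱼ > 0 (the conventional orientation; results are
invariant to the allele coding of the inputs). The intercept estimates the
average directional pleiotropic effect and its test is the pleiotropy
diagnostic; slope and intercept SEs carry the max(1, √(Q/(L−2))) inflation.

**Weighted median** — per-SNP ratios θ̂ⱼ weighted by (γ̂₁ⱼ/σ_Yⱼ)²,
normalised; the estimate interpolates the sorted ratios on the
cumulative-weight midpoint polyline at weight 0.5, and is consistent while
under half the total weight comes from invalid instruments. Its SE comes
from a parametric bootstrap (γ̂, Γ̂ resampled from normal distributions
centred on their estimates; default 1,000 replicates, mandatory seed — the
replicate count is a package choice).

**Multivariable IVW** — weighted least squares of Γ̂ on (γ̂₁, γ̂₂) with no
intercept and weights 1/σ_Yⱼ²; coefficients are the direct effects. SEs
carry the same multiplicative inflation with L−2 residual df. If one
exposure's betas are all exactly zero the design is singular and the fit
reduces to univariable IVW on the other exposure (the degenerate exposure
gets θ = 0 with infinite SE); any other rank deficiency is an error.

**Multivariable MR-Egger** — adds a free intercept (df L−3), records
oriented so γ̂₁ⱼ > 0.

**Q_a** — multivariable heterogeneity statistic
Σⱼ (Γ̂ⱼ − θ̂₁γ̂₁ⱼ − θ̂₂γ̂₂ⱼ)² / (σ_Yⱼ² + θ̂₁²σ₁ⱼ² + θ̂₂²σ₂ⱼ²), referred to
χ² with L−2 df; large values flag pleiotropy not absorbed by the
two-exposure model.

**Conditional F** — instrument strength for exposure 1 given exposure 2 is
the profiled statistic F = Q_x₁(δ̂)/(L−1), where
Q_x₁(δ) = Σⱼ (γ̂₁ⱼ − δγ̂₂ⱼ)² / (σ₁ⱼ² + δ²σ₂ⱼ² − 2δ·covⱼ) and δ̂ minimises
Q_x₁ by bounded scalar minimisation on [−100, 100] (tolerance 1e−8,
verified against a dense grid search in the tests). Values below 10 flag
conditional weak-instrument bias. Two caveats are worth recording. First,
this profiled objective is symmetric under δ → 1/δ, so the minimised Q — and
hence F — is identical for the two exposures whenever the optimum is
interior; implementations that instead plug in a regression-estimated δ
break this symmetry and can report different F per exposure. Second, when
the co-exposure's betas are all exactly zero δ is unidentified (the
numerator no longer depends on it) and profiling would drift to the bounds;
that case is detected and returns δ = 0 with the unconditional mean χ²,
Σ(γ̂₁ⱼ/σ₁ⱼ)²/(L−1). The per-SNP sampling covariance covⱼ between the two
exposure betas defaults to 0; because both exposures are typically measured
in the same sample, an option accepts a scalar phenotypic correlation r and
uses covⱼ = r·σ₁ⱼ·σ₂ⱼ for sensitivity analysis.

**Subgroup heterogeneity** — across strata (sexes, anatomical subsites),
Q = Σ (θ̂ₛ − θ̄)²/SEₛ² with θ̄ the inverse-variance-weighted pooled mean,
referred to χ² with S−1 df. SEs can be back-computed from printed CIs via
(ln upper − ln lower)/(2·z₀.₉₇₅).

**Instrument strength (univariable)** — F = R²(N−2)/(1−R²) per instrument,
with R² the variance explained and N the discovery sample size; when the
source GWAS reports no per-SNP R², the approximation
R²ⱼ = 2·eaf·(1−eaf)·βⱼ²/Var(trait) is used (Var(trait) configurable; the
three-category variable has variance 0.5 under the default cuts).

## Harmonization

SNPs are matched by rsid only (the motivating tables are rsid-keyed).
Records are aligned to the first exposure's effect allele: a swapped allele
pair flips the beta sign (and complements eaf); any other allele pair is
irreconcilable and the SNP is dropped with a logged reason code. All tables
are assumed coded on the forward strand, so palindromic (A/T, C/G) SNPs are
treated like any other by default; `strict_palindromes=True` additionally
drops palindromic SNPs whose eaf lies in (0.42, 0.58), where strand cannot
be checked from frequency. Instrument union for the multivariable analysis
takes the union of the two SNP lists and, when a user-supplied LD r² matrix
is given, applies the standard greedy clump: visit SNPs by ascending best
exposure p-value, keep a SNP only if its r² with every kept SNP is at or
below the threshold (default 0.001).

## Power

Analytic a priori power for a binary outcome uses the two-stage normal
approximation: with total outcome sample N, case fraction K, instrument
variance explained R² and odds ratio OR,
z = |ln OR|·√(N·R²·K(1−K)) and power = Φ(z − z₁₋α/₂). The minimum
detectable OR inverts this by bisection to 1e−6. Two caveats: the formula
treats the exposure-side associations as estimated without error (a good
approximation when the exposure GWAS is an order of magnitude larger than
the outcome sample, as here), and it assumes a unit-variance exposure — an
OR "per category" of a variable with variance 0.5 carries less information
than the formula credits. The simulation check in the test suite therefore
evaluates the formula on the standardized category scale, with a large
(100,000) exposure GWAS so neither nuisance clouds the comparison; the
agreement demonstrated there (within 0.03 of the empirical rejection rate
over 2,000 replicates) is for that idealised regime.

## Synthetic data

The generator emulates the motivating study's structure with defaults fixed
at its scale: 305 independent SNPs; true per-SNP effects on the two
exposures drawn bivariate normal with correlation ρ = 0.61 and rescaled so
the instruments explain exactly 4.5% and 6.4% of the two exposures'
variance; exposure GWAS of 453,169; outcome sample of 52,775 cases and
45,940 controls; true direct effects θ₁ = 0 (early life) and θ₂ = ln 1.3
(adult) per category change; optional per-SNP pleiotropic outcome effects
drawn Normal(pleio_mean, pleio_sd). Effect alleles are oriented to be
exposure-1-increasing; because that orientation conditions on the sign of
g₁, the realized effect correlation should be assessed with the
coding-invariant (uncentered) correlation, which joint per-SNP sign flips
preserve.

*Summary path* (`simulate_summary`): observed betas are drawn around their
true values with analytic SEs — exposure √(Var(c)/(2p(1−p)N)), outcome
log-odds √((1/n_cases + 1/n_controls)/(2p(1−p))) — the standard two-sample
simulation design. *Individual path* (`simulate_individual`): genotypes are
Binomial(2, maf) with maf uniform on (0.05, 0.5); a unit-variance latent
trait (genotype score plus normal noise) is cut at its 25th and 75th
percentiles into three ordered categories — a dominant "about average"
middle group; the true category proportions of the motivating cohort are not
published, so these cuts are configurable placeholders — and per-SNP OLS of
category on genotype gives the exposure tables. An independent outcome
sample gets case status from a logistic model with the configured
per-category direct effects and per-allele pleiotropic effects, intercept
set for the target case fraction; per-SNP log-odds estimates use the
one-step score approximation (Newton step from the null), the standard fast
GWAS method, accurate for the small per-allele effects simulated here. The
latent-to-category coarsening is handled analytically: the slope of
category on latent is Σ φ(Φ⁻¹(cut)) and variance-explained targets refer to
the category scale, so both paths agree on the per-category estimand. The
environmental components of the two latent traits are independent (only the
genetic correlation is modelled); the per-SNP sampling covariance between
the two exposure GWAS betas that same-sample estimation induces is therefore
absent, which is also why the conditional-F covariance option defaults
to 0. The path is capped at 10⁶ simulated individuals.

What passing tests on these data do **not** show about real data: no LD
between instruments (the study's instruments are clumped to r² < 0.001, so
independence is the intended regime, but residual LD in real panels is not
emulated), no sample overlap, no population stratification, no winner's
curse from instrument discovery, exact normality of effect distributions,
and no allele-frequency differences between samples.

## Calibration conventions

The directional-pleiotropy (Egger intercept) test is calibrated under
*balanced* pleiotropy — mean-zero per-SNP outcome effects (sd 0.005, about
half the typical outcome-beta SE at the study's scale), where the intercept
is truly zero and the multiplicative overdispersion inflation must absorb
the extra scatter. Q_a, by contrast, is a *test for* pleiotropy, so its
null is the no-pleiotropy model. Both are required to reject at 3–7% at
nominal 5% over 1,000 seeded replicates.

## Problem sizes

The test suite's stochastic checks use: 2,000 replicates for the power
oracle (10,000/10,000 outcome sample, 10-SNP instrument, 100,000-person
exposure GWAS); 200 replicates of the 300-SNP study-scale scenario for the
mediation/parameter-recovery check; 1,000 replicates for diagnostic
calibration; and 25–400 replicates for smaller cross-path and type-I-error
checks. These sizes put Monte-Carlo error well inside each check's
tolerance while keeping the default run practical on one CPU.

## Known limitations

- Matching is rsid-only; no positional fallback or proxy-SNP lookup.
- At most two simultaneous exposures; no MVMR-median/LASSO, MR-PRESSO,
  mode-based estimators, leave-one-out, or Steiger filtering.
- Normal (not t) inference throughout; at small L the CIs are anticonservative.
- The weighted-median bootstrap resamples independently per SNP; it does not
  model exposure–outcome sampling covariance (none in a two-sample design).
- LD clumping consumes a user-supplied r² matrix; the package never computes
  LD from genotypes.
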