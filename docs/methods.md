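# Methods

## The estimand and the triangulation design

The quantity of interest is the causal effect of arsenic metabolism
efficiency, measured as DMA% (the percentage of dimethylarsinic acid among
urinary arsenic species), on DNA methylation beta-values at CpG sites
previously found associated with arsenic exposure. Efficient metabolizers
excrete arsenic faster, so at a fixed external exposure their internal dose
is lower; if an EWAS association is causal, the efficiency→methylation
effect must therefore have the *opposite* sign to the arsenic→methylation
association. The pipeline triangulates this prediction across predictors of
increasing robustness to confounding: directly measured DMA%, the weighted
genetic score GP-DMA%, a weight-free binary genotype score, single SNPs,
and formal two-sample MR estimates. Because per-CpG power is low, the
inferential unit is not any single CpG but the *count* of sign-consistent
CpGs, tested against chance with an exact binomial test.

## Generative model of the synthetic cohort

The generator (`arsmr.synthetic`) encodes the hypothesized causal diagram:

* **Genotypes.** Three biallelic SNPs under Hardy–Weinberg equilibrium,
  effect (high-efficiency) allele frequencies 0.88 / 0.85 / 0.90. The first
  two (the 10q24.32 pair) may be drawn from a two-locus haplotype
  distribution with D = r·√(p₁q₁p₂q₂); the default r = 0.3 is a documented
  guess standing in for "moderate LD" — no published r is available. A
  requested r outside the feasibility bounds implied by the frequencies is
  rejected with the feasible range in the message.
* **Covariates.** age ~ N(40, 10²) clipped to 18–75; sex ~ Bernoulli(½);
  smoking never/former/current with probabilities 0.60/0.08/0.32;
  BMI ~ N(20.5, 3²); education ~ rounded Gamma(2, 2.5) capped at 16 years;
  four methylation batches; a binary two-cohort indicator. Smoking and
  cohort shift both exposure and methylation, injecting confounding that
  the covariate-adjusted models must remove.
* **Exposure.** ln(urinary arsenic, µg/g creatinine) ~ N(5.3, 0.85²) plus
  smoking/cohort shifts; water arsenic is a noisy correlate; creatinine is
  log-normal. The defaults put the median near 190 µg/g, matching the
  heavily exposed cohorts this design emulates.
* **DMA%.** dma = 65 + Σⱼ βⱼXⱼ + δ·ln U + ε, ε ~ N(0, 7.5²), truncated to
  (0.1, 99.9) (truncation events are logged, not resampled). δ = −1.5
  makes efficiency decline slightly with exposure; with the other defaults
  this yields corr(DMA%, ln U) ≈ −0.16 and a DMA% median/IQR matching the
  published cohort, which is the generator's calibration target.
* **Internal dose.** I = ln U − λ·DMA% with λ = 0.05 per percentage point.
  The functional form is a modelling choice (linear on the log scale) made
  for analytic tractability; no published form exists. λ > 0 encodes
  "efficiency lowers dose"; λ = 0 severs the causal path entirely, which
  is how the null studies are built.
* **Methylation.** For CpG c: logit(mᶜ) = αᶜ + θᶜ·I + covariate terms +
  N(0, 0.35²), inverse-logit transformed, guaranteeing beta-values in
  (0, 1). A fraction `frac_causal` of CpGs get θᶜ ~ N(0, 0.1²) (zero
  otherwise); intercepts are uniform over mean beta-values 0.1–0.9;
  per-CpG covariate and batch coefficients are N(0, 0.03²). The truth
  table records θᶜ and its sign.

The CpG architecture (which CpGs are causal, their effects, intercepts and
covariate loadings) is drawn from a sub-seed of the configuration seed and
can be *shared* across cohorts. The discovery-EWAS emulation uses this: a
fresh 800-person cohort with the same CpG biology is simulated and each
CpG regressed on ln U (covariate-adjusted), giving realistic, noisy EWAS
signs and a Bonferroni tier, exactly the kind of input table the analysis
stage consumes. A single integer seed drives per-stage substreams; the same
(config, seed) reproduces every table bit for bit.

What the generator does **not** emulate: array probe chemistry and type
I/II bias, batch distortions of the beta distribution, cell-type
composition, surrogate-variable structure, and fine-scale LD beyond the
one instrumented pair. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated causal model, not robustness to
array artefacts.

## Genetic scores

GP-DMA% is the exact dot product of high-efficiency allele counts with the
per-allele weights — no intercept, no standardization (the raw score is
the analysis variable). Missing genotypes are never imputed: samples
lacking any instrument drop out of score-based analyses only
(complete-case per analysis, so n varies across analyses by design). The
shipped default weights file is labelled synthetic in its header: the
published coefficient table is not machine-readable in the source text, so
the betas (2.9, 1.4, 4.4 percentage points; SEs 0.6, 0.5, 0.8) were
calibrated to reproduce the published score *levels* — maximum 17.4
relative to a zero-carrier baseline, with quartile steps of 1.4 (one
rs11191527 low-efficiency allele) and 2.9 (one rs9527 allele) — and the
stated facts that rs9527/rs61735836 carry large effects and rare
low-efficiency alleles. The binary score is 1 only for samples homozygous
high-efficiency at both rs9527 and rs61735836.

## Per-CpG regression models

Covariate sets are fixed declaratively: every model adjusts for age, sex,
batch and smoking (reference level: never); combined-cohort models add the
cohort indicator; DMA% and log-DMA models (restricted to the cohort with
urinary speciation) add BMI, education and ln water arsenic; the log-DMA
model further adds ln urinary arsenic and ln urinary creatinine. "Log"
transforms are natural logs; the outcome is the untransformed beta-value —
both defaults are flagged here because the alternative conventions
(log₂, M-values) are equally defensible. Single-SNP predictors are
carrier-collapsed (minor homozygotes merged with heterozygotes, oriented so
1 = higher effect-allele count), and the two 10q24.32 SNPs always enter one
model together, with the slope reported for the SNP named. Inference is
homoskedastic OLS with t-based p-values on n − p degrees of freedom;
designs are checked for rank and the collinear columns named on failure.
Mass fits across CpGs reuse one QR decomposition of the shared design
matrix; tests pin this path to statsmodels per-CpG output at 1e-10.

## MR estimators

β_X comes from the weights table (the prior study's effects), β_Y from
this pipeline's **additive** allele-count regressions — the Wald ratio
β_Y/β_X requires both sides per allele, so the carrier-collapsed models
used for single-SNP hypothesis tests are not reused here. The IVW
estimator is fixed-effect; with three instruments the heterogeneity
estimate is too unstable to justify random effects by default, but a
multiplicative random-effects option (se inflation by max(1, √(Q/(J−1))))
is provided. The Wald se is first-order (se_y/|β_x|), ignoring exposure
uncertainty and the Taylor second-order term. The ML estimator maximizes
the profile likelihood
ℓ(θ) = −½ Σⱼ (β_Yⱼ − θβ_Xⱼ)² / (se²_Yⱼ + θ²se²_Xⱼ)
(the per-SNP true effects ξⱼ maximize out in closed form), by BFGS from
the IVW start with gradient tolerance 1e-8 in standardized units — the
summary statistics are rescaled internally (β_X by its RMS, β_Y by the
median se_Y) because an absolute gradient tolerance is meaningless across
unit scales, and θ is exactly equivariant under this rescaling. The se
comes from the observed information (numerical curvature at the optimum).
Egger regression and median/mode estimators are deliberately absent:
three instruments cannot identify them.

## Directional consistency

A CpG is consistent when sign(estimate) = −sign(EWAS beta). An estimate of
exactly zero — a probability-zero event for continuous estimators —
counts as inconsistent, the conservative choice under the one-sided
alternative. The test is the exact binomial upper tail P(X ≥ k),
X ~ Binomial(n, ½), computed via the survival function; at n ≈ 200 the
normal approximation is off in the digits the results are reported to,
so no approximation is used. The null is implemented as the point null
p = ½ (the standard reduction of the composite "no more than chance"
null, and the form that reproduces reported values). One-sided direction
is fixed a priori: more consistent than chance.

## Simulation studies and problem sizes

The null-calibration study runs 100 replicates at n = 1,000 samples ×
200 CpGs with frac_causal = 0, λ = 0 and δ = 0; the concordance fraction
must sit inside the 3σ binomial band around ½ and the binomial p must
exceed 0.01 in at least 95% of replicates. The signal study runs 200
replicates at n = 2,000 × 200 CpGs with frac_causal = 0.6 and default λ;
IVW 95% intervals must cover the generative effect in ≥ 90% of causal
CpG × replicate pairs, and the GP-DMA% and IVW binomial tests must reject
(p < 0.05) in ≥ 90% of replicates. The coverage target on the observable
scale is defined by the delta method, −λ·θᶜ·E[mᶜ(1−mᶜ)] with the realized
per-CpG methylation mean — the generative effect is linear on the logit
scale, so its beta-scale image is only locally linear; at the default
effect sizes the induced approximation error is an order of magnitude
below the estimator's se. These sizes complete in a few minutes on one
CPU; the acceptance script uses 50/100 replicates for the same quantities.

## Known limitations

* The exclusion-restriction assumption (instruments act on methylation
  only through metabolism efficiency) is encoded as true in the generator;
  the pipeline measures estimation error under that assumption, not
  robustness to its violation.
* Homoskedastic OLS standard errors; beta-value outcomes are
  heteroskedastic near the boundary, which the logit-scale generator
  reproduces, so real-data users may prefer robust ses (not implemented).
* The ML MR se is a curvature estimate; profile-likelihood intervals are
  not implemented.
* Weights-file effect alleles are placeholder letters; harmonization
  against real genotype files must be done by the user upstream.
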