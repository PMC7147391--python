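# arsmr — Mendelian randomization for arsenic metabolism and DNA methylation

Chronic arsenic exposure from drinking water alters blood DNA methylation
at hundreds of CpG sites, but observational associations cannot show that
those changes are causal. Arsenic metabolism efficiency — measured as the
share of dimethylarsinic acid among urinary arsenic species, **DMA%** —
controls the internal arsenic dose at a given exposure, and DMA% has known
genetic determinants: two variants in the 10q24.32/*AS3MT* region (rs9527,
rs11191527) and one in *FTCD* (rs61735836). Those variants can serve as
instrumental variables, turning the question into a two-sample Mendelian
randomization (MR) problem.

`arsmr` implements that triangulation as a tested, reusable pipeline for
epidemiologists and statistical geneticists:

1. **Genetic scores.** The weighted genetically predicted DMA% score
   GP-DMA% = Σⱼ β_Xⱼ·Xⱼ, where Xⱼ counts high-efficiency alleles and β_Xⱼ
   is the per-allele effect on DMA%, plus a weight-free binary score
   (homozygous high-efficiency at both large-effect SNPs).
2. **Per-CpG associations.** Homoskedastic OLS of methylation beta-values
   on each efficiency predictor under fixed covariate sets (age, sex,
   batch, smoking; plus cohort when cohorts are combined; plus BMI,
   education and log water arsenic for directly measured DMA%). Minor
   alleles are carrier-collapsed for single-SNP models, and the two
   10q24.32 SNPs in LD are always modeled jointly.
3. **Two-sample MR.** Per CpG, SNP→DMA% weights (β_Xⱼ, se) are combined
   with this pipeline's SNP→CpG estimates (β_Yⱼ, se) by the fixed-effect
   inverse-variance-weighted estimator
   θ̂ = Σⱼ β_Xⱼβ_Yⱼ/se²_Yⱼ ÷ Σⱼ β²_Xⱼ/se²_Yⱼ,
   and by maximum likelihood over the model β_Xⱼ ~ N(ξⱼ, se²_Xⱼ),
   β_Yⱼ ~ N(θξⱼ, se²_Yⱼ), which also propagates exposure-side uncertainty.
4. **Directional consistency.** Because higher efficiency lowers internal
   dose, an estimate is *consistent* with a prior arsenic EWAS when its
   sign is opposite the EWAS sign. With k consistent CpGs out of n, the
   exact one-sided binomial p is P(X ≥ k), X ~ Binomial(n, ½).
5. **Synthetic cohorts.** A generator with the causal chain
   genotype → DMA% → internal dose → methylation (plus smoking/cohort
   confounding) and a truth table, so every stage — and the whole pipeline's
   error rates — can be validated without access to any real cohort.

The shipped default weights file is **synthetic**: per-allele effects
calibrated to the published score distribution (see its header), not
transcribed coefficients. Point `--weights` at your own TSV for real use.

## Worked example

```bash
arsmr run-all --out-dir demo --seed 11
```

simulates a 772-sample, 221-CpG cohort, runs all analyses, and prints the
summary table (abridged):

```
        analysis_label  k_consistent  n_total   binomial_p
               dma_pct           162      221 1.366817e-12
                gp_dma           137      221 2.215216e-04
          binary_score           128      221 1.098852e-02
    snp_carrier:rs9527           115      221 2.952910e-01
snp_carrier:rs11191527           108      221 6.567007e-01
snp_carrier:rs61735836           136      221 3.668205e-04
                   ivw           138      221 1.313726e-04
                    ml           138      221 1.313726e-04
```

Read: of 221 arsenic-associated CpGs, the IVW MR estimate opposed the
EWAS sign at 138 (one-sided binomial p = 1.3 × 10⁻⁴) — efficiency-raising
genotypes shift methylation against the arsenic direction far more often
than chance, exactly the pattern expected if the EWAS associations are
causal. Directly measured DMA% (which also absorbs non-genetic variation)
is stronger still; the weakly associated instrument rs11191527 is, as
expected, uninformative on its own. Stage outputs (`cohort/`, `scores.tsv`,
`associations.tsv`, `mr_estimates.tsv`, `consistency.tsv`, `manifest.json`)
land under `demo/`; rerunning with the same seed reproduces them byte for
byte. Each stage is also available separately (`arsmr simulate | score |
associate | mr | consistency`) and as library functions.

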