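"""Synthetic arsenic-exposure cohorts with known causal structure.

The generator emulates a Bangladeshi-style arsenic cohort in which three
biallelic SNPs raise arsenic metabolism efficiency (DMA%, the share of
dimethylarsinic acid among urinary arsenic species), efficiency lowers the
internal arsenic dose at a given exposure, and the internal dose shifts
methylation at a known subset of CpGs with known signs:

    genotype --> DMA% --> internal dose --> methylation
                   ^           ^
                   +-- ln(urinary As) --+

Smoking and cohort membership confound exposure and methylation. Every
quantity downstream of the seed is reproducible bit for bit, and the truth
table records which CpGs are causal and with what sign, so the whole
score -> regression -> MR -> sign-concordance pipeline can be validated
without any real genotype or array data.

Default parameters are calibrated to the published cohort anchors: median
DMA% ~72, DMA% interquartile width ~11 percentage points, median urinary
arsenic ~200 ug/g creatinine, and corr(DMA%, ln urinary As) ~ -0.16.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

SMOKING_LEVELS = ("never", "former", "current")
DMA_TRUNC = (0.1, 99.9)


@dataclass(frozen=True)
class SNPSpec:
    """A simulated instrument SNP: effect-allele (high-efficiency) frequency
    and per-allele effect on DMA% in percentage points."""

    snp_id: str
    effect_allele_freq: float
    beta_dma: float
    se_beta_dma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.effect_allele_freq < 1.0:
            raise ValueError(f"{self.snp_id}: effect_allele_freq must be in (0,1)")
        if not self.se_beta_dma > 0:
            raise ValueError(f"{self.snp_id}: se_beta_dma must be > 0")


def default_snp_specs() -> list[SNPSpec]:
    """Three instruments mirroring the shipped weights file: two SNPs in the
    10q24.32 region (first two, eligible for LD) and one exonic variant.
    Effect alleles are common, so low-efficiency alleles are the minor ones."""
    return [
        SNPSpec("rs9527", 0.88, 2.9, 0.60),
        SNPSpec("rs11191527", 0.85, 1.4, 0.50),
        SNPSpec("rs61735836", 0.90, 4.4, 0.80),
    ]


@dataclass
class SimConfig:
    """Parameters of the generative model.

    The exposure block is log-normal urinary arsenic (ug/g creatinine);
    ``delta_dma_on_logAs`` couples DMA% to ln exposure (negative, so that
    heavily exposed individuals methylate slightly less efficiently);
    ``lambda_dose`` is the per-percentage-point reduction of log internal
    dose with DMA%. Causal CpG effects act on the logit of methylation.
    """

    n_samples: int = 772
    n_cpgs: int = 221
    frac_causal: float = 0.6
    snp_specs: list[SNPSpec] = field(default_factory=default_snp_specs)
    ld_r: float = 0.3
    dma_baseline: float = 65.0
    dma_noise_sd: float = 7.5
    exposure_log_mean: float = 5.3
    exposure_log_sd: float = 0.85
    delta_dma_on_logAs: float = -1.5
    lambda_dose: float = 0.05
    effect_sd: float = 0.1
    covariate_effect_sd: float = 0.03
    logit_noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_cpgs < 1:
            raise ValueError("n_samples and n_cpgs must be positive")
        if not 0.0 <= self.frac_causal <= 1.0:
            raise ValueError("frac_causal must be in [0,1]")
        if not -1.0 <= self.ld_r <= 1.0:
            raise ValueError("ld_r must be in [-1,1]")
        for name in ("dma_noise_sd", "exposure_log_sd", "effect_sd", "logit_noise_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.lambda_dose < 0:
            raise ValueError("lambda_dose must be >= 0")
        if len(self.snp_specs) < 1:
            raise ValueError("at least one SNPSpec required")

    @property
    def n_causal(self) -> int:
        return int(round(self.frac_causal * self.n_cpgs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snp_specs"] = [asdict(s) for s in self.snp_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["snp_specs"] = [SNPSpec(**s) for s in d.get("snp_specs", [])] or default_snp_specs()
        return cls(**d)


@dataclass
class CohortTable:
    """Aligned per-sample data: covariates/exposures/DMA% in ``samples``
    (indexed by sample_id), effect-allele counts in ``genotype`` (samples x
    SNPs; NaN = missing), and beta-values in ``methylation`` (CpGs x samples).
    """

    samples: pd.DataFrame
    genotype: pd.DataFrame
    methylation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.genotype.index):
            raise ValueError("samples and genotype tables are not sample-aligned")
        if list(self.methylation.columns) != list(self.samples.index):
            raise ValueError("methylation columns are not sample-aligned")

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.methylation.index


def ld_r_bounds(f1: float, f2: float) -> tuple[float, float]:
    """Feasible haplotype-correlation range for two loci with the given
    effect-allele frequencies (all four haplotype frequencies nonnegative)."""
    q1, q2 = 1 - f1, 1 - f2
    s = np.sqrt(f1 * q1 * f2 * q2)
    return (-min(f1 * f2, q1 * q2) / s, min(f1 * q2, q1 * f2) / s)


def simulate_genotypes(
    specs: list[SNPSpec],
    n: int,
    ld_r: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Effect-allele counts for ``n`` samples under Hardy-Weinberg.

    Each SNP is marginally Binomial(2, f). When ``ld_r`` is nonzero and at
    least two SNPs are present, the first two SNPs' haplotypes are drawn
    jointly with D = ld_r * sqrt(f1 q1 f2 q2), reproducing the requested
    haplotype correlation; remaining SNPs are independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = {}
    paired = ld_r != 0.0 and len(specs) >= 2
    if paired:
        f1, f2 = specs[0].effect_allele_freq, specs[1].effect_allele_freq
        lo, hi = ld_r_bounds(f1, f2)
        if not lo <= ld_r <= hi:
            raise ValueError(
                f"ld_r={ld_r} infeasible for frequencies ({f1}, {f2}); "
                f"feasible range is [{lo:.4f}, {hi:.4f}]"
            )
        d = ld_r * np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
        # haplotypes: (1,1), (1,0), (0,1), (0,0) on the effect alleles
        hap_p = np.array(
            [f1 * f2 + d, f1 * (1 - f2) - d, (1 - f1) * f2 - d, (1 - f1) * (1 - f2) + d]
        )
        hap_p = np.clip(hap_p, 0.0, None)
        hap_p /= hap_p.sum()
        haps = rng.choice(4, size=(n, 2), p=hap_p)
        a1 = np.isin(haps, (0, 1)).sum(axis=1)  # carries effect allele at locus 1
        a2 = np.isin(haps, (0, 2)).sum(axis=1)
        counts[specs[0].snp_id] = a1
        counts[specs[1].snp_id] = a2
        rest = specs[2:]
    else:
        rest = specs
    for s in rest:
        counts[s.snp_id] = rng.binomial(2, s.effect_allele_freq, size=n)
    df = pd.DataFrame(counts, columns=[s.snp_id for s in specs])
    df.index = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    return df


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(40.0, 10.0, n), 18, 75)
    sex = rng.binomial(1, 0.5, n)  # 1 = female
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=[0.60, 0.08, 0.32])
    bmi = np.clip(rng.normal(20.5, 3.0, n), 13, 40)
    education = np.minimum(np.round(rng.gamma(2.0, 2.5, n)), 16).astype(int)
    batch = rng.choice([f"B{i}" for i in range(1, 5)], size=n)
    cohort = rng.binomial(1, 0.5, n)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "smoking": pd.Categorical(smoking, categories=list(SMOKING_LEVELS)),
            "bmi": bmi,
            "education": education,
            "batch": pd.Categorical(batch),
            "cohort": cohort,
        }
    )


@dataclass
class CpGParams:
    """The CpG-level causal architecture: which CpGs respond to internal
    dose (and how strongly), their baseline logit-methylation, and their
    per-CpG covariate/batch coefficients. Drawn once per seed so that an
    analysis cohort and a discovery-EWAS cohort share the same biology."""

    truth: pd.DataFrame
    intercept: np.ndarray
    cov_coef: np.ndarray
    batch_coef: np.ndarray


def draw_cpg_params(config: SimConfig) -> CpGParams:
    """CpG architecture as a pure function of (seed, n_cpgs, frac_causal,
    effect scales) — independent of the sample draw."""
    m = config.n_cpgs
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC96]))
    cpg_ids = [f"cg{i:07d}" for i in range(m)]
    causal_idx = rng.choice(m, size=config.n_causal, replace=False)
    true_effect = np.zeros(m)
    if config.n_causal:
        eff = rng.normal(0.0, config.effect_sd, config.n_causal)
        eff[eff == 0.0] = config.effect_sd  # probability-zero guard
        true_effect[causal_idx] = eff
    truth = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "is_causal": true_effect != 0.0,
            "true_sign": np.sign(true_effect).astype(int),
            "true_effect": true_effect,
        }
    )
    intercept = rng.uniform(logit(0.1), logit(0.9), m)
    cov_coef = rng.normal(0.0, config.covariate_effect_sd, (m, 5))
    batch_coef = rng.normal(0.0, config.covariate_effect_sd, (m, 4))
    return CpGParams(truth, intercept, cov_coef, batch_coef)


def simulate_cohort(
    config: SimConfig, cpg_params: CpGParams | None = None
) -> tuple[CohortTable, pd.DataFrame]:
    """Draw one cohort plus its truth table.

    Generative chain: DMA% = baseline + sum_j beta_j X_j + delta * ln U +
    noise (truncated to (0.1, 99.9)); internal dose I = ln U - lambda * DMA%;
    causal CpGs have logit(beta-value) linear in I with the recorded sign.
    Smoking and cohort shift both ln U and methylation (confounding).
    The truth table has columns cpg_id, is_causal, true_sign, true_effect
    (logit-scale effect of I; 0 for non-causal CpGs).

    Passing ``cpg_params`` reuses a previously drawn CpG architecture, so
    two cohorts (e.g. a discovery EWAS sample and the analysis sample) can
    share causal structure while differing in every individual.
    """
    ss = np.random.SeedSequence(config.seed)
    r_geno, r_cov, r_expo, r_dma, r_meth = [np.random.default_rng(s) for s in ss.spawn(5)]
    n, m = config.n_samples, config.n_cpgs
    params = cpg_params if cpg_params is not None else draw_cpg_params(config)
    if len(params.truth) != m:
        raise ValueError("cpg_params drawn for a different n_cpgs")

    genotype = simulate_genotypes(config.snp_specs, n, config.ld_r, r_geno)
    cov = _simulate_covariates(n, r_cov)
    cov.index = genotype.index

    current = (cov["smoking"] == "current").to_numpy(float)
    former = (cov["smoking"] == "former").to_numpy(float)
    cohort_ind = cov["cohort"].to_numpy(float)

    # exposure block: smoking and cohort confound urinary arsenic
    ln_u = (
        config.exposure_log_mean
        + 0.15 * current
        + 0.05 * former
        - 0.20 * cohort_ind
        + r_expo.normal(0.0, config.exposure_log_sd, n)
    )
    ln_w = 0.8 * (ln_u - config.exposure_log_mean) + r_expo.normal(4.0, 0.6, n)
    creatinine = np.exp(r_expo.normal(np.log(0.6), 0.4, n))

    betas = np.array([s.beta_dma for s in config.snp_specs])
    dma_raw = (
        config.dma_baseline
        + genotype.to_numpy(float) @ betas
        + config.delta_dma_on_logAs * ln_u
        + r_dma.normal(0.0, config.dma_noise_sd, n)
    )
    n_trunc = int(((dma_raw <= DMA_TRUNC[0]) | (dma_raw >= DMA_TRUNC[1])).sum())
    if n_trunc:
        logger.info("truncated DMA%% for %d of %d samples to (%.1f, %.1f)", n_trunc, n, *DMA_TRUNC)
    dma = np.clip(dma_raw, *DMA_TRUNC)

    dose = ln_u - config.lambda_dose * dma

    truth = params.truth
    true_effect = truth["true_effect"].to_numpy()
    age_std = (cov["age"].to_numpy() - 40.0) / 10.0
    z = np.column_stack([age_std, cov["sex"].to_numpy(float), former, current, cohort_ind])
    batch_codes = cov["batch"].cat.codes.to_numpy()

    lg = (
        params.intercept[:, None]
        + true_effect[:, None] * dose[None, :]
        + params.cov_coef @ z.T
        + params.batch_coef[:, batch_codes]
        + r_meth.normal(0.0, config.logit_noise_sd, (m, n))
    )
    meth = expit(lg)
    np.clip(meth, 1e-12, 1 - 1e-12, out=meth)
    methylation = pd.DataFrame(
        meth, index=pd.Index(truth["cpg_id"], name="cpg_id"), columns=genotype.index
    )

    samples = cov.assign(
        water_as=np.exp(ln_w),
        urinary_as=np.exp(ln_u),
        urinary_creatinine=creatinine,
        dma_pct=dma,
    )
    return CohortTable(samples, genotype, methylation), truth


def make_ewas_table(
    config: SimConfig,
    seed: int | None = None,
    n_discovery: int = 800,
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """Emulate the prior discovery EWAS on an independent cohort.

    Draws a fresh cohort from ``config`` (discovery substream) and regresses
    each CpG's beta-value on ln urinary arsenic adjusted for age, sex,
    smoking, batch and cohort, giving the (noisy) arsenic-association signs
    the downstream concordance analyses take as input. CpGs whose discovery
    p passes ``bonferroni_alpha / n_cpgs`` are tiered ``bonferroni_set``,
    the rest ``fdr_set``. Returns columns cpg_id, ewas_beta, ewas_se,
    ewas_p, tier; zero betas (never observed in practice) would be invalid
    downstream and raise here.
    """
    from .association import fit_many, build_design

    base = config.seed if seed is None else seed
    # shared CpG architecture, fresh individuals for the discovery sample
    params = draw_cpg_params(config)
    disc_seed = int(np.random.SeedSequence([base, 0xE3A5]).generate_state(1)[0] % 2**31)
    cfg_dict = config.to_dict()
    cfg_dict.update(n_samples=n_discovery, seed=disc_seed)
    disc_cfg = SimConfig.from_dict(cfg_dict)
    cohort, _ = simulate_cohort(disc_cfg, cpg_params=params)
    df = cohort.samples.assign(ln_urinary_as=np.log(cohort.samples["urinary_as"]))
    x = build_design(df, "ln_urinary_as", ["age", "sex", "smoking", "batch", "cohort"])
    res = fit_many(cohort.methylation, x, predictor="ln_urinary_as")
    if (res["beta"] == 0).any():
        raise ValueError("degenerate discovery EWAS: zero effect estimate")
    tier = np.where(
        res["p"] < bonferroni_alpha / config.n_cpgs, "bonferroni_set", "fdr_set"
    )
    return pd.DataFrame(
        {
            "cpg_id": res["cpg_id"],
            "ewas_beta": res["beta"],
            "ewas_se": res["se"],
            "ewas_p": res["p"],
            "tier": tier,
        }
    )


def write_cohort(cohort: CohortTable, truth: pd.DataFrame | None, out_dir: str | Path) -> dict[str, Path]:
    """Write genotypes/covariates/methylation (and truth) as TSVs.

    Genotype values are integer allele counts with missing entries as empty
    fields; methylation rows are CpGs, columns sample ids.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "covariates": out / "covariates.tsv",
        "methylation": out / "methylation.tsv",
    }
    geno = cohort.genotype.astype("Int64")
    geno.to_csv(paths["genotypes"], sep="\t", na_rep="")
    cohort.samples.to_csv(paths["covariates"], sep="\t")
    cohort.methylation.to_csv(paths["methylation"], sep="\t", float_format="%.6g")
    if truth is not None:
        paths["truth"] = out / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
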