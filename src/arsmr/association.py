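"""Per-CpG linear-model associations of methylation with efficiency predictors.

Each analysis regresses a CpG's beta-value on one predictor of arsenic
metabolism efficiency under a fixed, declarative covariate set:

=================  ===========================  ==================================
predictor          restriction                  covariates
=================  ===========================  ==================================
dma_pct            cohort 1 only (has DMA%)     age, sex, batch, smoking, bmi,
                                                education, ln water As
log_dma            cohort 1 only                dma_pct set + ln urinary As,
                                                ln urinary creatinine
gp_dma             combined cohorts             age, sex, batch, smoking, cohort
binary_score       combined cohorts             same as gp_dma
snp_carrier:<id>   combined cohorts             same as gp_dma; the two SNPs in
                                                LD enter the model together
snp_additive:<id>  combined cohorts             as snp_carrier but allele counts
                                                (per-allele slopes for MR)
=================  ===========================  ==================================

Outcomes are untransformed beta-values; inference is homoskedastic OLS with
t-based two-sided p-values. Single fits go through statsmodels; analyses
over many CpGs share one design matrix, so slopes and standard errors for
all CpGs come from a single least-squares solve (tested to agree with
statsmodels to near machine precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import scores as _scores
from .synthetic import CohortTable

BASE_COVARIATES = ("age", "sex", "batch", "smoking")

PREDICTOR_MODELS: dict[str, dict] = {
    "dma_pct": {
        "covariates": BASE_COVARIATES + ("bmi", "education", "ln_water_as"),
        "cohort_restriction": "cohort1_only",
    },
    "log_dma": {
        "covariates": BASE_COVARIATES
        + ("bmi", "education", "ln_water_as", "ln_urinary_as", "ln_urinary_creatinine"),
        "cohort_restriction": "cohort1_only",
    },
    "gp_dma": {"covariates": BASE_COVARIATES + ("cohort",), "cohort_restriction": "combined"},
    "binary_score": {"covariates": BASE_COVARIATES + ("cohort",), "cohort_restriction": "combined"},
}


@dataclass(frozen=True)
class ModelSpec:
    """A named analysis: predictor, covariate list, cohort restriction and
    (for single-SNP models) extra jointly adjusted SNP terms."""

    predictor: str
    covariates: tuple[str, ...]
    cohort_restriction: str = "combined"
    joint_snps: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.predictor in self.covariates:
            raise ValueError(f"predictor {self.predictor!r} also listed as covariate")
        if self.cohort_restriction not in ("combined", "cohort1_only"):
            raise ValueError(f"unknown cohort_restriction {self.cohort_restriction!r}")


def model_spec(name: str) -> ModelSpec:
    """Build the standard ModelSpec for a predictor name.

    ``snp_carrier:<id>`` / ``snp_additive:<id>`` give single-SNP models;
    when <id> is one of the LD pair, the other member enters jointly.
    """
    if name in PREDICTOR_MODELS:
        cfg = PREDICTOR_MODELS[name]
        return ModelSpec(name, tuple(cfg["covariates"]), cfg["cohort_restriction"])
    for prefix in ("snp_carrier:", "snp_additive:"):
        if name.startswith(prefix):
            snp = name[len(prefix):]
            joint = tuple(s for s in _scores.LD_PAIR if s != snp) if snp in _scores.LD_PAIR else ()
            return ModelSpec(name, BASE_COVARIATES + ("cohort",), "combined", joint)
    raise KeyError(f"unknown analysis name {name!r}")


@dataclass(frozen=True)
class AssociationResult:
    cpg_id: str
    predictor: str
    beta: float
    se: float
    t: float
    p: float
    n_used: int


def build_design(samples: pd.DataFrame, predictor: str, covariates: list[str] | tuple[str, ...],
                 extra: list[str] | tuple[str, ...] = ()) -> pd.DataFrame:
    """Numeric design matrix: const, predictor, extra terms, then covariates
    with categoricals dummy-coded against their first level (smoking
    reference = never)."""
    cols = [predictor, *extra]
    parts = [samples[cols].astype(float)]
    for cov in covariates:
        col = samples[cov]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).to_frame(cov))
    x = pd.concat(parts, axis=1)
    x.insert(0, "const", 1.0)
    return x


def _check_full_rank(x: pd.DataFrame) -> None:
    arr = x.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via QR pivoting on the scaled matrix
        scaled = arr / np.maximum(np.abs(arr).max(axis=0), 1e-300)
        _, r = np.linalg.qr(scaled)
        bad = [x.columns[j] for j in range(arr.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def fit_cpg_model(y: np.ndarray | pd.Series, design: pd.DataFrame,
                  cpg_id: str = "", predictor: str | None = None) -> AssociationResult:
    """OLS of one CpG's beta-values on the design; returns the slope for
    ``predictor`` (default: first non-constant column) with homoskedastic
    se, t, and two-sided p on n - p degrees of freedom."""
    y = np.asarray(y, float)
    n, p = design.shape
    if n <= p + 1:
        raise ValueError(f"too few complete cases (n={n}) for {p} parameters")
    _check_full_rank(design)
    if predictor is None:
        predictor = next(c for c in design.columns if c != "const")
    res = sm.OLS(y, design.to_numpy(float)).fit()
    j = list(design.columns).index(predictor)
    return AssociationResult(
        cpg_id=cpg_id,
        predictor=predictor,
        beta=float(res.params[j]),
        se=float(res.bse[j]),
        t=float(res.tvalues[j]),
        p=float(res.pvalues[j]),
        n_used=int(n),
    )


def fit_many(methylation: pd.DataFrame, design: pd.DataFrame,
             predictor: str | None = None) -> pd.DataFrame:
    """Mass-fit one OLS design against every CpG row of ``methylation``.

    All CpGs share the design matrix, so the normal equations are solved
    once for a multi-column response. Returns a frame with columns cpg_id,
    beta, se, t, p, n_used for the predictor term.
    """
    n, p = design.shape
    if n <= p + 1:
        raise ValueError(f"too few complete cases (n={n}) for {p} parameters")
    _check_full_rank(design)
    if predictor is None:
        predictor = next(c for c in design.columns if c != "const")
    j = list(design.columns).index(predictor)

    x = design.to_numpy(float)
    y = methylation.to_numpy(float).T  # n x m
    q, r = np.linalg.qr(x)
    coef = np.linalg.solve(r, q.T @ y)  # p x m
    resid = y - x @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv_jj = np.linalg.inv(r.T @ r)[j, j]
    se = np.sqrt(sigma2 * xtx_inv_jj)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef[j] / se, np.inf * np.sign(coef[j]))
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame(
        {
            "cpg_id": methylation.index,
            "predictor": predictor,
            "beta": coef[j],
            "se": se,
            "t": t,
            "p": pvals,
            "n_used": n,
        }
    ).reset_index(drop=True)


def _snp_binary(counts: pd.Series) -> pd.Series:
    """Carrier-collapsed single-SNP predictor oriented on higher effect-allele
    count: minor-allele homozygotes merge with heterozygotes, and the binary
    is 1 for the group with more effect alleles."""
    obs = counts.dropna()
    freq = obs.mean() / 2.0
    if freq > 0.5:  # effect allele is major; carriers of the minor allele -> 0
        coded = (counts == 2).astype(float)
    else:  # effect allele is minor; its carriers -> 1
        coded = (counts >= 1).astype(float)
    coded[counts.isna()] = np.nan
    return coded


def prepare_analysis_frame(cohort: CohortTable, spec: ModelSpec) -> tuple[pd.DataFrame, str, list[str]]:
    """Assemble the per-sample frame for one analysis: derived predictor
    column, log-transformed exposure covariates, complete cases only.
    Returns (frame, predictor column name, extra jointly-adjusted terms)."""
    df = cohort.samples.copy()
    df["ln_water_as"] = np.log(df["water_as"])
    df["ln_urinary_as"] = np.log(df["urinary_as"])
    df["ln_urinary_creatinine"] = np.log(df["urinary_creatinine"])
    df["log_dma"] = np.log(df["dma_pct"])

    extra: list[str] = []
    name = spec.predictor
    if name.startswith("snp_carrier:") or name.startswith("snp_additive:"):
        snp = name.split(":", 1)[1]
        if snp not in cohort.genotype.columns:
            raise KeyError(f"cohort lacks genotypes for {snp!r}")
        carrier = name.startswith("snp_carrier:")
        main = _snp_binary(cohort.genotype[snp]) if carrier else cohort.genotype[snp].astype(float)
        pred_col = f"{'carrier' if carrier else 'count'}_{snp}"
        df[pred_col] = main
        for other in spec.joint_snps:
            term = _snp_binary(cohort.genotype[other]) if carrier else cohort.genotype[other].astype(float)
            col = f"{'carrier' if carrier else 'count'}_{other}"
            df[col] = term
            extra.append(col)
    elif name in ("gp_dma", "binary_score"):
        if name not in df.columns:
            raise KeyError(f"cohort samples table lacks a {name!r} column; compute scores first")
        pred_col = name
    elif name in ("dma_pct", "log_dma"):
        pred_col = name
    else:
        raise KeyError(f"unknown predictor {name!r}")

    if spec.cohort_restriction == "cohort1_only":
        df = df[df["cohort"] == 0]

    needed = [pred_col, *extra, *spec.covariates]
    if spec.cohort_restriction == "cohort1_only" and "cohort" in needed:
        needed.remove("cohort")  # constant after restriction
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    return df[needed].copy(), pred_col, extra


def run_analysis(cohort: CohortTable, spec: ModelSpec | str,
                 cpg_list: list[str] | None = None) -> pd.DataFrame:
    """Fit one analysis across CpGs, returning per-CpG summary statistics.

    Unknown CpG ids are skipped with a warning; samples incomplete for the
    model's variables are dropped (complete-case), so n_used varies across
    analyses exactly as per-measure availability varies in real cohorts.
    """
    if isinstance(spec, str):
        spec = model_spec(spec)
    frame, pred_col, extra = prepare_analysis_frame(cohort, spec)
    covs = [c for c in spec.covariates
            if not (spec.cohort_restriction == "cohort1_only" and c == "cohort")]
    design = build_design(frame, pred_col, covs, extra)
    meth = cohort.methylation
    if cpg_list is not None:
        known = [c for c in cpg_list if c in meth.index]
        unknown = sorted(set(cpg_list) - set(known))
        if unknown:
            warnings.warn(f"skipping {len(unknown)} unknown CpG ids (e.g. {unknown[:3]})")
        meth = meth.loc[known]
    out = fit_many(meth[frame.index], design, predictor=pred_col)
    out["predictor"] = spec.predictor
    return out
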