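"""Two-sample summary-statistic Mendelian randomization estimators.

Inputs are per-instrument summary pairs: the SNP's effect on the exposure
(DMA%, from a prior genetic study) and its effect on the outcome (a CpG's
methylation beta-value, from this pipeline's regressions), both oriented on
the same effect allele. Three estimators of the causal effect theta
(beta-value change per percentage point DMA%) are provided:

* Wald ratio — single instrument, beta_y / beta_x with first-order se.
* IVW — fixed-effect inverse-variance weighting of Wald ratios, equal to
  the slope of a no-intercept regression of beta_y on beta_x with weights
  1/se_y^2. A multiplicative random-effects variant inflates the se by the
  root of the heterogeneity mean square when it exceeds one.
* Maximum likelihood — maximizes the bivariate normal likelihood with free
  per-SNP true exposure effects xi_j (beta_x_j ~ N(xi_j, se_x_j^2),
  beta_y_j ~ N(theta xi_j, se_y_j^2)); xi_j profiles out in closed form,
  leaving a one-dimensional profile likelihood in theta. Unlike IVW, this
  accounts for uncertainty in the exposure associations.

With only three instruments, pleiotropy-robust estimators (Egger, weighted
median) are not identified and are intentionally absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class InstrumentSummary:
    """One SNP's aligned exposure and outcome associations."""

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float

    def __post_init__(self) -> None:
        if not self.se_x > 0 or not self.se_y > 0:
            raise ValueError(f"{self.snp_id}: standard errors must be > 0")


@dataclass(frozen=True)
class MREstimate:
    cpg_id: str
    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_instruments: int


def _estimate(cpg_id: str, method: str, theta: float, se: float, n: int) -> MREstimate:
    z = theta / se
    return MREstimate(
        cpg_id=cpg_id,
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z975 * se),
        ci_high=float(theta + Z975 * se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=n,
    )


def wald_ratio(inst: InstrumentSummary, cpg_id: str = "") -> MREstimate:
    """theta = beta_y / beta_x with first-order se = se_y / |beta_x|
    (exposure uncertainty ignored); normal confidence interval."""
    if inst.beta_x == 0:
        raise ValueError(f"{inst.snp_id}: Wald ratio undefined for beta_x = 0")
    theta = inst.beta_y / inst.beta_x
    se = inst.se_y / abs(inst.beta_x)
    return _estimate(cpg_id, "wald", theta, se, 1)


def ivw_estimate(instruments: list[InstrumentSummary], cpg_id: str = "",
                 random_effects: bool = False) -> MREstimate:
    """Fixed-effect IVW: theta = sum(bx*by/sy^2) / sum(bx^2/sy^2) with
    se = sqrt(1 / sum(bx^2/sy^2)); reduces to the Wald ratio for a single
    instrument. ``random_effects=True`` applies the multiplicative
    heterogeneity inflation max(1, sqrt(Q/(J-1))) to the se."""
    if not instruments:
        raise ValueError("IVW requires at least one instrument")
    bx = np.array([i.beta_x for i in instruments])
    by = np.array([i.beta_y for i in instruments])
    sy = np.array([i.se_y for i in instruments])
    if np.all(bx == 0):
        raise ValueError("all beta_x are zero: causal effect not identified")
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    theta = np.sum(w * bx * by) / denom
    se = np.sqrt(1.0 / denom)
    if random_effects and len(instruments) > 1:
        q = float(np.sum(w * (by - theta * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (len(instruments) - 1)))
    return _estimate(cpg_id, "ivw", theta, se, len(instruments))


def ml_profile_loglik(theta: float | np.ndarray, instruments: list[InstrumentSummary]) -> float | np.ndarray:
    """Profile log-likelihood in theta (per-SNP xi_j maximized out):
    -1/2 * sum_j (beta_y_j - theta*beta_x_j)^2 / (se_y_j^2 + theta^2*se_x_j^2),
    up to an additive constant."""
    bx = np.array([i.beta_x for i in instruments])
    by = np.array([i.beta_y for i in instruments])
    sx2 = np.array([i.se_x for i in instruments]) ** 2
    sy2 = np.array([i.se_y for i in instruments]) ** 2
    th = np.asarray(theta, float)[..., None]
    val = -0.5 * np.sum((by - th * bx) ** 2 / (sy2 + th**2 * sx2), axis=-1)
    return float(val) if np.ndim(theta) == 0 else val


def _ml_gradient(theta: float, instruments: list[InstrumentSummary]) -> float:
    bx = np.array([i.beta_x for i in instruments])
    by = np.array([i.beta_y for i in instruments])
    sx2 = np.array([i.se_x for i in instruments]) ** 2
    sy2 = np.array([i.se_y for i in instruments]) ** 2
    v = sy2 + theta**2 * sx2
    r = by - theta * bx
    return float(np.sum(r * bx / v) + np.sum(r**2 * theta * sx2 / v**2))


def ml_estimate(instruments: list[InstrumentSummary], cpg_id: str = "",
                max_iter: int = 200, gtol: float = 1e-8) -> MREstimate:
    """Maximum-likelihood theta via quasi-Newton ascent of the profile
    likelihood from the IVW start, converged when the gradient norm falls
    below ``gtol``; se from the observed information (numerical curvature
    of the profile log-likelihood at the optimum).

    Internally the summary statistics are standardized (beta_x by its RMS,
    beta_y by the median se_y) so the gradient tolerance is meaningful at
    any unit scale; theta is exactly equivariant under this rescaling, so
    the back-transformed estimate is unchanged.
    """
    if not instruments:
        raise ValueError("ML requires at least one instrument")
    ax = float(np.sqrt(np.mean([i.beta_x**2 for i in instruments]))) or 1.0
    ay = float(np.median([i.se_y for i in instruments]))
    scaled = [
        InstrumentSummary(i.snp_id, i.beta_x / ax, i.se_x / ax, i.beta_y / ay, i.se_y / ay)
        for i in instruments
    ]
    start = ivw_estimate(scaled, cpg_id).theta
    res = optimize.minimize(
        lambda t: -ml_profile_loglik(float(t[0]), scaled),
        x0=[start],
        jac=lambda t: np.array([-_ml_gradient(float(t[0]), scaled)]),
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    grad_final = abs(_ml_gradient(float(res.x[0]), scaled))
    # BFGS may stop with a line-search precision warning while already at
    # the optimum; accept if the gradient is at noise level.
    if not res.success and grad_final > 1e-6:
        raise RuntimeError(f"ML MR failed to converge for {cpg_id or '<cpg>'}: {res.message}; "
                           f"trace: nit={res.nit}, grad={res.jac}")
    th_s = float(res.x[0])
    h = 1e-5 * (1.0 + abs(th_s))
    curv = (_ml_gradient(th_s + h, scaled) - _ml_gradient(th_s - h, scaled)) / (2 * h)
    if curv >= 0:
        raise RuntimeError(f"non-concave profile likelihood at optimum for {cpg_id or '<cpg>'}")
    se_s = float(np.sqrt(-1.0 / curv))
    unit = ay / ax
    return _estimate(cpg_id, "ml", th_s * unit, se_s * unit, len(instruments))


def instruments_from_tables(weights, snp_associations: pd.DataFrame, cpg_id: str) -> list[InstrumentSummary]:
    """Join a weights list (snp_id, beta_dma, se) with per-SNP outcome
    regressions (columns snp_id, cpg_id, beta, se) for one CpG."""
    rows = snp_associations[snp_associations["cpg_id"] == cpg_id]
    out = []
    for w in weights:
        match = rows[rows["snp_id"] == w.snp_id]
        if len(match) != 1:
            raise ValueError(f"expected one outcome association for {w.snp_id}/{cpg_id}, got {len(match)}")
        r = match.iloc[0]
        out.append(InstrumentSummary(w.snp_id, w.beta_dma, w.se, float(r["beta"]), float(r["se"])))
    return out


def mr_all(weights, snp_associations: pd.DataFrame, methods: tuple[str, ...] = ("ivw", "ml"),
           random_effects: bool = False) -> pd.DataFrame:
    """Run the requested MR methods for every CpG present in the per-SNP
    outcome association table; returns one row per CpG x method."""
    fns = {
        "ivw": lambda inst, cid: ivw_estimate(inst, cid, random_effects=random_effects),
        "ml": ml_estimate,
        "wald": lambda inst, cid: wald_ratio(inst[0], cid),
    }
    unknown = set(methods) - set(fns)
    if unknown:
        raise KeyError(f"unknown MR methods: {sorted(unknown)}")
    records = []
    for cpg_id in pd.unique(snp_associations["cpg_id"]):
        inst = instruments_from_tables(weights, snp_associations, cpg_id)
        for m in methods:
            records.append(fns[m](inst, cpg_id).__dict__)
    return pd.DataFrame.from_records(records)
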