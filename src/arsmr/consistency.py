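"""Sign concordance between efficiency associations and a prior arsenic EWAS.

Efficient arsenic metabolism lowers internal dose, so a CpG truly pushed by
arsenic should associate with an efficiency measure (DMA%, a genetic score,
or an MR estimate) in the direction *opposite* to its previously reported
arsenic-exposure association. Each CpG is coded consistent/inconsistent by
that rule, and enrichment of consistent calls is tested with an exact
one-sided binomial test against chance probability 1/2 (upper tail: more
consistent than chance). The exact tail is used throughout — at the sample
sizes involved (tens to low hundreds of CpGs) the normal approximation is
visibly off in the reported digits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConsistencySummary:
    analysis_label: str
    k_consistent: int
    n_total: int
    binomial_p_one_sided: float
    per_cpg_flags: dict[str, str]

    def __post_init__(self) -> None:
        if not 0 <= self.k_consistent <= self.n_total:
            raise ValueError("k_consistent must be in [0, n_total]")


def code_direction(estimate_beta: float, ewas_beta: float) -> str:
    """'consistent' iff the estimate's sign is opposite the EWAS sign.

    A zero estimate (probability-zero for continuous estimators) counts as
    inconsistent — the conservative call under the one-sided alternative.
    A zero EWAS beta leaves the direction undefined and is an error.
    """
    if ewas_beta == 0 or not np.isfinite(ewas_beta):
        raise ValueError("EWAS beta of 0 (or non-finite) has no direction")
    if not np.isfinite(estimate_beta):
        raise ValueError("estimate beta must be finite")
    return "consistent" if np.sign(estimate_beta) == -np.sign(ewas_beta) else "inconsistent"


def binomial_one_sided(k: int, n: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Binomial(n, 1/2), via the
    survival function (numerically stable; no normal approximation)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    return float(stats.binom.sf(k - 1, n, 0.5))


def binomial_one_sided_lower(k: int, n: int) -> float:
    """Exact lower-tail P(X <= k); complements the upper tail at k+1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        return 0.0
    return float(stats.binom.cdf(k, n, 0.5))


def summarize_consistency(
    estimates: pd.DataFrame,
    ewas: pd.DataFrame,
    label: str,
    tier: str | None = None,
    beta_col: str | None = None,
) -> ConsistencySummary:
    """Code every estimate against the EWAS sign and binomial-test the count.

    ``estimates`` needs columns cpg_id plus an effect column (``beta`` for
    regression output, ``theta`` for MR output — auto-detected unless
    ``beta_col`` is given). ``ewas`` needs cpg_id, ewas_beta and (if
    ``tier`` is requested) a tier column; restricting to a tier subsets the
    analysis to those CpGs, mirroring the Bonferroni-restricted sensitivity
    analyses. Estimates for CpGs absent from the EWAS table are an error;
    duplicated CpG ids are rejected.
    """
    if estimates["cpg_id"].duplicated().any():
        dups = estimates.loc[estimates["cpg_id"].duplicated(), "cpg_id"].tolist()
        raise ValueError(f"duplicate CpG ids in estimates: {dups[:5]}")
    if ewas["cpg_id"].duplicated().any():
        raise ValueError("duplicate CpG ids in EWAS table")
    if beta_col is None:
        beta_col = "theta" if "theta" in estimates.columns else "beta"

    ewas_use = ewas if tier is None else ewas[ewas["tier"] == tier]
    merged = estimates.merge(ewas_use[["cpg_id", "ewas_beta"]], on="cpg_id", how="inner")
    if tier is None and len(merged) < len(estimates):
        missing = sorted(set(estimates["cpg_id"]) - set(ewas["cpg_id"]))
        raise ValueError(f"{len(missing)} CpGs missing from EWAS table (e.g. {missing[:5]})")

    flags = {
        str(r.cpg_id): code_direction(getattr(r, beta_col), r.ewas_beta)
        for r in merged.itertuples()
    }
    k = sum(f == "consistent" for f in flags.values())
    n = len(flags)
    if n == 0:
        raise ValueError(f"no CpGs to summarize for label {label!r}")
    return ConsistencySummary(label, k, n, binomial_one_sided(k, n), flags)


def consistency_table(summaries: list[ConsistencySummary]) -> pd.DataFrame:
    """One row per analysis label: k consistent, n total, one-sided p."""
    return pd.DataFrame(
        [
            {
                "analysis_label": s.analysis_label,
                "k_consistent": s.k_consistent,
                "n_total": s.n_total,
                "binomial_p": s.binomial_p_one_sided,
            }
            for s in summaries
        ]
    )
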