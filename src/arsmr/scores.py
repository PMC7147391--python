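"""Genetically predicted DMA% scores from SNP weights.

The weighted score (GP-DMA%) is the sum over instrument SNPs of the
high-efficiency allele count times that SNP's published per-allele effect
on DMA%. It measures the genetically predicted increase in arsenic
metabolism efficiency relative to an arbitrary zero-carrier baseline; no
intercept or standardization is applied.

A supplementary binary score flags individuals who are homozygous for the
high-efficiency allele at both large-effect SNPs (rs9527 and rs61735836),
avoiding weights entirely.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BINARY_SCORE_SNPS = ("rs9527", "rs61735836")

#: SNPs in moderate LD at 10q24.32 that are jointly adjusted in
#: single-SNP regression models.
LD_PAIR = ("rs9527", "rs11191527")


@dataclass(frozen=True)
class SNPWeight:
    """One instrument: identity, high-efficiency (effect) allele, and its
    per-allele effect on DMA% with standard error (percentage points)."""

    snp_id: str
    effect_allele: str
    beta_dma: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")


def default_weights_path() -> Path:
    """Path to the shipped default weights file.

    The shipped file is synthetic: per-allele effects calibrated to the
    published score distribution, not transcribed coefficients (see the
    file header).
    """
    ref = importlib.resources.files("arsmr").joinpath("data/snp_weights_synthetic.tsv")
    return Path(str(ref))


def load_weights(path: str | Path | None = None) -> list[SNPWeight]:
    """Read a weights TSV (columns snp_id, effect_allele, beta_dma, se;
    ``#`` comment lines allowed). ``None`` loads the shipped default."""
    if path is None:
        path = default_weights_path()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "effect_allele": str})
    required = {"snp_id", "effect_allele", "beta_dma", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weights file {path} missing columns: {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id in weights file: {dups}")
    return [
        SNPWeight(row.snp_id, row.effect_allele, float(row.beta_dma), float(row.se))
        for row in df.itertuples()
    ]


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if np.isnan(counts.astype(float)).any():
        raise ValueError(
            "missing genotypes must be handled by complete-case exclusion "
            "upstream, not passed to scoring"
        )
    if not np.isin(counts, (0, 1, 2)).all():
        bad = np.unique(counts[~np.isin(counts, (0, 1, 2))])
        raise ValueError(f"allele counts must be in {{0,1,2}}, got {bad}")
    return counts


def weighted_score(genotype_row: pd.Series | dict, weights: list[SNPWeight]) -> float:
    """GP-DMA% for one sample: sum_j beta_j * x_j over effect-allele counts.

    ``genotype_row`` must be keyed by snp_id and coded on each SNP's
    high-efficiency allele; an id absent from the row is a hard error
    (alignment bugs must not silently score as zero).
    """
    row = dict(genotype_row)
    total = 0.0
    for w in weights:
        if w.snp_id not in row:
            raise KeyError(f"genotype row lacks instrument SNP {w.snp_id!r}")
        count = _check_counts(np.asarray([row[w.snp_id]]))[0]
        total += w.beta_dma * float(count)
    return total


def weighted_scores(genotypes: pd.DataFrame, weights: list[SNPWeight]) -> pd.Series:
    """Vectorized GP-DMA% over a samples x SNPs allele-count table."""
    ids = [w.snp_id for w in weights]
    missing = [s for s in ids if s not in genotypes.columns]
    if missing:
        raise KeyError(f"genotype table lacks instrument SNPs {missing}")
    counts = _check_counts(genotypes[ids].to_numpy())
    betas = np.array([w.beta_dma for w in weights])
    return pd.Series(counts @ betas, index=genotypes.index, name="gp_dma")


def binary_score(genotype_row: pd.Series | dict) -> int:
    """1 iff the sample is homozygous for the high-efficiency allele at
    BOTH rs9527 and rs61735836; any low-efficiency allele at either SNP
    gives 0. rs11191527 plays no role."""
    row = dict(genotype_row)
    for snp in BINARY_SCORE_SNPS:
        if snp not in row:
            raise KeyError(f"genotype row lacks {snp!r} needed for the binary score")
    counts = _check_counts(np.array([row[s] for s in BINARY_SCORE_SNPS]))
    return int((counts == 2).all())


def binary_scores(genotypes: pd.DataFrame) -> pd.Series:
    missing = [s for s in BINARY_SCORE_SNPS if s not in genotypes.columns]
    if missing:
        raise KeyError(f"genotype table lacks {missing} needed for the binary score")
    counts = _check_counts(genotypes[list(BINARY_SCORE_SNPS)].to_numpy())
    return pd.Series((counts == 2).all(axis=1).astype(int), index=genotypes.index, name="binary_score")


def carrier_collapse(counts: np.ndarray | pd.Series, minor_is_effect: bool = True) -> np.ndarray:
    """Collapse an additive genotype to minor-allele-carrier coding.

    Minor-allele homozygotes are merged with heterozygotes, so the output
    is 1 for samples carrying at least one minor allele and 0 otherwise.
    When ``minor_is_effect`` is False the counts are already coded on the
    major allele and carrier status refers to the complementary allele
    (count < 2).
    """
    arr = _check_counts(np.asarray(counts))
    if minor_is_effect:
        return (arr >= 1).astype(int)
    return (arr < 2).astype(int)


def orient_minor(counts: np.ndarray | pd.Series) -> tuple[np.ndarray, bool]:
    """Return counts recoded on the minor allele plus a flag saying whether
    the input was already minor-coded (resolved from the sample allele
    frequency; ties treated as minor-coded)."""
    arr = _check_counts(np.asarray(counts))
    freq = arr.mean() / 2.0
    if freq <= 0.5:
        return arr, True
    return 2 - arr, False


def score_table(genotypes: pd.DataFrame, weights: list[SNPWeight]) -> pd.DataFrame:
    """Per-sample score table with columns sample_id, gp_dma, binary_score.

    Samples with any missing instrument genotype must already have been
    dropped (complete-case); NaNs raise.
    """
    out = pd.DataFrame(
        {
            "sample_id": genotypes.index.astype(str),
            "gp_dma": weighted_scores(genotypes, weights).to_numpy(),
            "binary_score": binary_scores(genotypes).to_numpy(),
        }
    )
    return out
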