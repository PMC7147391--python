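"""End-to-end orchestration: simulate -> score -> associate -> MR -> consistency.

``run_all`` executes the full triangulation over the five predictor models
(DMA%, log DMA, weighted genetic score, binary score, per-SNP carriers)
plus IVW and maximum-likelihood MR, writing every stage's table as TSV and
a manifest with the config hash so a run is reproducible byte for byte
from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association, consistency, mr, scores
from .synthetic import CohortTable, SimConfig, make_ewas_table, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

#: analysis labels of the consistency summary table, in report order
ANALYSIS_LABELS = (
    "dma_pct",
    "log_dma",
    "gp_dma",
    "binary_score",
    "snp_carrier:rs9527",
    "snp_carrier:rs11191527",
    "snp_carrier:rs61735836",
    "ivw",
    "ml",
)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_outputs: dict[str, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def config_hash(config: SimConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def load_cohort(directory: str | Path) -> CohortTable:
    """Read a cohort written by ``write_cohort`` (or assembled by hand),
    inner-joining the three tables on sample_id.

    Missing genotypes stay NaN and drop a sample only from analyses that
    need that SNP (complete-case per analysis). Duplicated sample ids or a
    <2-sample overlap abort.
    """
    d = Path(directory)
    geno = pd.read_csv(d / "genotypes.tsv", sep="\t", index_col="sample_id")
    cov = pd.read_csv(d / "covariates.tsv", sep="\t", index_col="sample_id")
    meth = pd.read_csv(d / "methylation.tsv", sep="\t", index_col="cpg_id")
    for name, idx in (("genotypes", geno.index), ("covariates", cov.index)):
        if idx.duplicated().any():
            raise ValueError(f"duplicated sample ids in {name}")
    common = geno.index.intersection(cov.index).intersection(meth.columns)
    common.name = "sample_id"
    logger.info(
        "cohort load: %d genotype, %d covariate, %d methylation samples; %d overlap",
        len(geno), len(cov), meth.shape[1], len(common),
    )
    if len(common) < 2:
        raise ValueError(f"only {len(common)} samples shared across input files")
    cov = cov.loc[common]
    if "smoking" in cov.columns:
        cov["smoking"] = pd.Categorical(cov["smoking"], categories=["never", "former", "current"])
    if "batch" in cov.columns:
        cov["batch"] = pd.Categorical(cov["batch"])
    return CohortTable(cov, geno.loc[common].astype(float), meth[common])


def attach_scores(cohort: CohortTable, weights: list[scores.SNPWeight]) -> pd.DataFrame:
    """Add gp_dma / binary_score columns to the samples table (NaN where a
    needed genotype is missing, so those samples drop out complete-case)."""
    geno = cohort.genotype
    inst = [w.snp_id for w in weights]
    complete = geno[inst].notna().all(axis=1)
    gp = pd.Series(np.nan, index=geno.index, name="gp_dma")
    if complete.any():
        gp[complete] = scores.weighted_scores(geno.loc[complete, inst].astype(int), weights)
    bsnps = list(scores.BINARY_SCORE_SNPS)
    bin_complete = geno[bsnps].notna().all(axis=1)
    bs = pd.Series(np.nan, index=geno.index, name="binary_score")
    if bin_complete.any():
        bs[bin_complete] = scores.binary_scores(geno.loc[bin_complete, bsnps].astype(int))
    cohort.samples["gp_dma"] = gp
    cohort.samples["binary_score"] = bs
    return cohort.samples


def snp_outcome_associations(cohort: CohortTable, weights: list[scores.SNPWeight]) -> pd.DataFrame:
    """Per-allele SNP -> CpG regressions feeding the two-sample MR: one
    additive-coded model per instrument (the LD pair jointly adjusted),
    returning columns snp_id, cpg_id, beta, se."""
    frames = []
    for w in weights:
        res = association.run_analysis(cohort, f"snp_additive:{w.snp_id}")
        res.insert(0, "snp_id", w.snp_id)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def run_all(
    config: SimConfig,
    out_dir: str | Path,
    weights: list[scores.SNPWeight] | None = None,
    tiers: tuple[str | None, ...] = (None, "bonferroni_set"),
) -> RunManifest:
    """Execute the full pipeline on a synthetic cohort and write all stage
    outputs under ``out_dir``. Returns the run manifest.

    ``weights`` defaults to the generative SNP effects (the synthetic
    analogue of weights taken from a prior publication); pass a list loaded
    from a weights TSV to decouple the two samples further.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(config), seed=config.seed,
                           versions={"arsmr": __version__, "weights": "generative" if weights is None else "file"})

    def stamp(stage: str) -> None:
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    try:
        # stage 1: simulate
        cohort, truth = simulate_cohort(config)
        paths = write_cohort(cohort, truth, out / "cohort")
        manifest.stage_outputs.update({k: str(v) for k, v in paths.items()})
        stamp("simulate")

        if weights is None:
            weights = [scores.SNPWeight(s.snp_id, "NA", s.beta_dma, s.se_beta_dma)
                       for s in config.snp_specs]

        # stage 2: scores
        attach_scores(cohort, weights)
        score_path = out / "scores.tsv"
        cohort.samples[["gp_dma", "binary_score"]].to_csv(score_path, sep="\t")
        manifest.stage_outputs["scores"] = str(score_path)
        stamp("score")

        # stage 3: prior-EWAS emulation (input to consistency coding)
        ewas = make_ewas_table(config)
        ewas_path = out / "ewas.tsv"
        ewas.to_csv(ewas_path, sep="\t", index=False)
        manifest.stage_outputs["ewas"] = str(ewas_path)
        stamp("ewas")

        # stage 4: per-CpG associations for each predictor model
        assoc_frames: dict[str, pd.DataFrame] = {}
        for label in ANALYSIS_LABELS:
            if label in ("ivw", "ml"):
                continue
            res = association.run_analysis(cohort, label)
            assoc_frames[label] = res
            logger.info("analysis %s: n_used=%d", label, res["n_used"].iloc[0])
        assoc_path = out / "associations.tsv"
        pd.concat(assoc_frames.values(), ignore_index=True).to_csv(assoc_path, sep="\t", index=False)
        manifest.stage_outputs["associations"] = str(assoc_path)
        stamp("associate")

        # stage 5: two-sample MR from summary statistics
        snp_assoc = snp_outcome_associations(cohort, weights)
        mr_res = mr.mr_all(weights, snp_assoc, methods=("ivw", "ml"))
        mr_path = out / "mr_estimates.tsv"
        mr_res.to_csv(mr_path, sep="\t", index=False)
        manifest.stage_outputs["mr"] = str(mr_path)
        stamp("mr")

        # stage 6: directional consistency per analysis label
        summaries = []
        flag_rows = []
        for tier in tiers:
            if tier is not None and not (ewas["tier"] == tier).any():
                continue  # tier subset can be empty for small simulations
            suffix = "" if tier is None else f":{tier}"
            for label in ANALYSIS_LABELS:
                if label in ("ivw", "ml"):
                    est = mr_res[mr_res["method"] == label]
                else:
                    est = assoc_frames[label]
                s = consistency.summarize_consistency(est, ewas, label + suffix, tier=tier)
                summaries.append(s)
                flag_rows.extend(
                    {"analysis_label": s.analysis_label, "cpg_id": c, "flag": f}
                    for c, f in s.per_cpg_flags.items()
                )
        summary = consistency.consistency_table(summaries)
        summary_path = out / "consistency.tsv"
        summary.to_csv(summary_path, sep="\t", index=False)
        pd.DataFrame(flag_rows).to_csv(out / "consistency_flags.tsv", sep="\t", index=False)
        manifest.stage_outputs["consistency"] = str(summary_path)
        manifest.stage_outputs["consistency_flags"] = str(out / "consistency_flags.tsv")
        stamp("consistency")
    except Exception as err:
        stage = len(manifest.timestamps)
        raise RuntimeError(
            f"pipeline failed after stage {stage} ({'/'.join(manifest.timestamps)}): {err}"
        ) from err

    manifest.write(out / "manifest.json")
    return manifest
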