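"""Per-CpG OLS: oracle equivalence, covariate sets, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arsmr import association
from arsmr.association import build_design, fit_cpg_model, fit_many, model_spec, run_analysis


def normal_equations_oracle(x: np.ndarray, y: np.ndarray, j: int):
    """Independent direct solve: beta = (X'X)^-1 X'y, homoskedastic se."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = x.shape[0] - x.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(s2 * xtx_inv[j, j])
    return beta[j], se


class TestFitCpgModel:
    def test_exact_noiseless_fit(self):
        pred = np.arange(10.0)
        y = 0.3 + 0.01 * pred
        x = pd.DataFrame({"const": 1.0, "pred": pred})
        res = fit_cpg_model(y, x, cpg_id="cg0")
        assert res.beta == pytest.approx(0.01, abs=1e-12)
        assert abs(res.t) > 1e6  # residual variance numerically zero

    def test_matches_normal_equations_oracle(self, toy_design):
        x, y = toy_design
        res = fit_cpg_model(y, x, predictor="pred")
        beta, se = normal_equations_oracle(x.to_numpy(float), y, list(x.columns).index("pred"))
        assert res.beta == pytest.approx(beta, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.t == pytest.approx(res.beta / res.se, rel=1e-12)

    def test_rank_deficient_names_columns(self, toy_design):
        x, y = toy_design
        x = x.assign(c1_copy=x["c1"])
        with pytest.raises(ValueError, match="c1"):
            fit_cpg_model(y, x)

    def test_too_few_samples(self):
        x = pd.DataFrame({"const": [1.0, 1, 1], "pred": [0.0, 1, 2], "c": [3.0, 1, 4]})
        with pytest.raises(ValueError, match="complete cases"):
            fit_cpg_model(np.zeros(3), x)


class TestFitMany:
    def test_agrees_with_statsmodels_per_cpg(self, rng):
        n, m = 40, 15
        x = pd.DataFrame({"const": 1.0, "pred": rng.normal(size=n), "c1": rng.normal(size=n)})
        meth = pd.DataFrame(rng.uniform(0.1, 0.9, (m, n)),
                            index=[f"cg{i}" for i in range(m)], columns=range(n))
        many = fit_many(meth, x, predictor="pred")
        for i, cpg in enumerate(meth.index):
            single = fit_cpg_model(meth.loc[cpg], x, cpg_id=cpg, predictor="pred")
            assert many.loc[i, "beta"] == pytest.approx(single.beta, abs=1e-10)
            assert many.loc[i, "se"] == pytest.approx(single.se, abs=1e-10)
            assert many.loc[i, "p"] == pytest.approx(single.p, rel=1e-8)

    def test_permutation_null_uniform_pvalues(self, rng):
        n, m = 100, 1000
        x = pd.DataFrame({"const": 1.0, "pred": rng.permutation(np.arange(n)).astype(float)})
        meth = pd.DataFrame(rng.uniform(0.2, 0.8, (m, n)), index=[f"cg{i}" for i in range(m)])
        meth.columns = x.index
        res = fit_many(meth, x, predictor="pred")
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_predictor_rescaling_equivariance(self, rng):
        n = 60
        pred = rng.normal(size=n)
        x1 = pd.DataFrame({"const": 1.0, "pred": pred})
        x2 = pd.DataFrame({"const": 1.0, "pred": pred * 10})
        meth = pd.DataFrame(rng.uniform(0.2, 0.8, (5, n)))
        meth.columns = x1.index
        r1 = fit_many(meth, x1, predictor="pred")
        r2 = fit_many(meth, x2, predictor="pred")
        assert np.allclose(r2["beta"], r1["beta"] / 10, rtol=1e-12)
        assert np.allclose(r2["t"], r1["t"], rtol=1e-10)

    def test_orthogonal_covariate_leaves_beta_unchanged(self, rng):
        n = 80
        pred = rng.normal(size=n)
        y = 0.4 + 0.05 * pred + rng.normal(0, 0.05, n)
        # orthogonalize a noise covariate against [1, pred, y]
        basis = np.column_stack([np.ones(n), pred, y])
        raw = rng.normal(size=n)
        ortho = raw - basis @ np.linalg.lstsq(basis, raw, rcond=None)[0]
        x1 = pd.DataFrame({"const": 1.0, "pred": pred})
        x2 = x1.assign(ortho=ortho)
        b1 = fit_cpg_model(y, x1, predictor="pred").beta
        b2 = fit_cpg_model(y, x2, predictor="pred").beta
        assert b2 == pytest.approx(b1, abs=1e-8)


class TestModelSpecs:
    def test_dma_model_covariates(self):
        spec = model_spec("dma_pct")
        assert spec.cohort_restriction == "cohort1_only"
        assert set(spec.covariates) == {
            "age", "sex", "batch", "smoking", "bmi", "education", "ln_water_as",
        }

    def test_log_dma_adds_urinary_terms(self):
        spec = model_spec("log_dma")
        assert {"ln_urinary_as", "ln_urinary_creatinine"} <= set(spec.covariates)

    def test_combined_models_adjust_for_cohort(self):
        for name in ("gp_dma", "binary_score", "snp_carrier:rs9527"):
            assert "cohort" in model_spec(name).covariates

    def test_ld_pair_jointly_adjusted(self):
        assert model_spec("snp_carrier:rs9527").joint_snps == ("rs11191527",)
        assert model_spec("snp_carrier:rs11191527").joint_snps == ("rs9527",)
        assert model_spec("snp_carrier:rs61735836").joint_snps == ()

    def test_predictor_cannot_be_covariate(self):
        with pytest.raises(ValueError):
            association.ModelSpec("age", ("age", "sex"))


class TestRunAnalysis:
    def test_design_and_restriction(self, small_cohort):
        _, cohort, _ = small_cohort
        res = run_analysis(cohort, "dma_pct")
        n_cohort1 = int((cohort.samples["cohort"] == 0).sum())
        assert (res["n_used"] == n_cohort1).all()
        assert len(res) == cohort.methylation.shape[0]

    def test_joint_snp_slope_is_for_named_snp(self, small_cohort):
        """The two 10q24.32 SNPs enter one model together; the reported
        slope must change with the SNP named, not the shared model."""
        _, cohort, _ = small_cohort
        r1 = run_analysis(cohort, "snp_carrier:rs9527")
        r2 = run_analysis(cohort, "snp_carrier:rs11191527")
        assert not np.allclose(r1["beta"], r2["beta"])

    def test_unknown_cpgs_skipped_with_warning(self, small_cohort):
        _, cohort, _ = small_cohort
        wanted = list(cohort.methylation.index[:5]) + ["cg_not_there"]
        with pytest.warns(UserWarning, match="unknown CpG"):
            res = run_analysis(cohort, "dma_pct", wanted)
        assert len(res) == 5

    def test_sign_recovery_on_causal_cpgs(self):
        """At large n the DMA% slope sign opposes the arsenic effect sign
        for nearly all causal CpGs (efficiency lowers internal dose)."""
        from arsmr.synthetic import SimConfig, simulate_cohort

        cfg = SimConfig(n_samples=4000, n_cpgs=120, frac_causal=0.6, seed=77)
        cohort, truth = simulate_cohort(cfg)
        res = run_analysis(cohort, "dma_pct").merge(truth, on="cpg_id")
        causal = res[res["is_causal"]]
        assert (np.sign(causal["beta"]) == -causal["true_sign"]).mean() >= 0.9
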