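"""Two-sample MR estimators against independent oracles and invariances."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from arsmr.mr import (
    InstrumentSummary,
    ivw_estimate,
    ml_estimate,
    ml_profile_loglik,
    wald_ratio,
)

THREE = [
    InstrumentSummary("rs9527", 2.9, 0.6, -0.004, 0.002),
    InstrumentSummary("rs11191527", 1.4, 0.5, -0.001, 0.0015),
    InstrumentSummary("rs61735836", 4.4, 0.8, -0.007, 0.003),
]


class TestWaldRatio:
    def test_definitional_arithmetic(self):
        est = wald_ratio(InstrumentSummary("s", 0.5, 0.1, 1.0, 0.2))
        assert est.theta == pytest.approx(2.0, abs=0)
        assert est.se == pytest.approx(0.4, abs=0)
        assert est.ci_low < est.theta < est.ci_high

    def test_zero_outcome_effect(self):
        assert wald_ratio(InstrumentSummary("s", 0.5, 0.1, 0.0, 0.2)).theta == 0.0

    def test_allele_flip_cancels(self):
        a = wald_ratio(InstrumentSummary("s", 0.5, 0.1, 1.0, 0.2))
        b = wald_ratio(InstrumentSummary("s", -0.5, 0.1, -1.0, 0.2))
        assert b.theta == pytest.approx(a.theta, abs=0)
        assert b.se == pytest.approx(a.se, abs=0)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError, match="beta_x"):
            wald_ratio(InstrumentSummary("s", 0.0, 0.1, 1.0, 0.2))


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        inst = InstrumentSummary("s", 0.7, 0.1, 0.35, 0.05)
        a, b = wald_ratio(inst), ivw_estimate([inst])
        assert b.theta == pytest.approx(a.theta, abs=1e-12)
        assert b.se == pytest.approx(a.se, abs=1e-12)

    def test_matches_weighted_regression_oracle(self):
        """IVW equals the slope of a no-intercept WLS of beta_y on beta_x
        with weights 1/se_y^2 (independent statsmodels route)."""
        bx = np.array([i.beta_x for i in THREE])
        by = np.array([i.beta_y for i in THREE])
        w = np.array([1 / i.se_y**2 for i in THREE])
        fit = sm.WLS(by, bx, weights=w).fit()
        est = ivw_estimate(THREE)
        assert est.theta == pytest.approx(fit.params[0], abs=1e-10)
        # fixed-effect se uses sigma2=1, i.e. the unscaled covariance
        assert est.se == pytest.approx(np.sqrt(fit.normalized_cov_params[0, 0]), abs=1e-10)

    def test_exact_proportionality(self):
        c = -0.0123
        insts = [
            InstrumentSummary(f"s{j}", bx, 0.1, c * bx, 0.01)
            for j, bx in enumerate((1.0, 2.0, 3.0))
        ]
        est = ivw_estimate(insts)
        assert est.theta == pytest.approx(c, rel=1e-12)
        heterogeneity = sum((i.beta_y - est.theta * i.beta_x) ** 2 for i in insts)
        assert heterogeneity == pytest.approx(0.0, abs=1e-20)

    def test_random_effects_never_shrinks_se(self):
        fe = ivw_estimate(THREE)
        re = ivw_estimate(THREE, random_effects=True)
        assert re.theta == fe.theta
        assert re.se >= fe.se

    def test_empty_and_unidentified(self):
        with pytest.raises(ValueError):
            ivw_estimate([])
        with pytest.raises(ValueError, match="identified"):
            ivw_estimate([InstrumentSummary("s", 0.0, 0.1, 0.1, 0.1)])


class TestML:
    def test_matches_ivw_when_exposure_noise_vanishes(self):
        insts = [
            InstrumentSummary(i.snp_id, i.beta_x, 1e-8 * i.se_y, i.beta_y, i.se_y)
            for i in THREE
        ]
        ml = ml_estimate(insts)
        ivw = ivw_estimate(insts)
        assert ml.theta == pytest.approx(ivw.theta, abs=1e-4 * abs(ivw.theta) + 1e-10)
        assert ml.se == pytest.approx(ivw.se, rel=1e-3)

    def test_single_symmetric_instrument(self):
        inst = InstrumentSummary("s", 1.0, 0.2, 1.0, 0.2)
        assert ml_estimate([inst]).theta == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        """Dense 1-D grid over theta with per-SNP xi profiled via its
        closed form, evaluating the full bivariate likelihood."""
        def joint_loglik(theta):
            total = 0.0
            for i in THREE:
                xi = (i.beta_x / i.se_x**2 + theta * i.beta_y / i.se_y**2) / (
                    1 / i.se_x**2 + theta**2 / i.se_y**2
                )
                total += -0.5 * ((i.beta_x - xi) / i.se_x) ** 2
                total += -0.5 * ((i.beta_y - theta * xi) / i.se_y) ** 2
            return total

        grid = np.linspace(-0.02, 0.02, 400001)
        vals = [joint_loglik(t) for t in grid]
        theta_grid = grid[int(np.argmax(vals))]
        est = ml_estimate(THREE)
        assert est.theta == pytest.approx(theta_grid, abs=1e-4)

    def test_profile_equals_joint_maximum_over_xi(self):
        theta = -0.0017
        prof = ml_profile_loglik(theta, THREE)
        brute = 0.0
        for i in THREE:
            xis = np.linspace(i.beta_x - 3, i.beta_x + 3, 200001)
            term = -0.5 * ((i.beta_x - xis) / i.se_x) ** 2 - 0.5 * (
                (i.beta_y - theta * xis) / i.se_y
            ) ** 2
            brute += term.max()
        assert prof == pytest.approx(brute, abs=1e-6)


class TestInvariances:
    @pytest.mark.parametrize("method", ["ivw", "ml"])
    @pytest.mark.parametrize("flip_mask", [(True, False, False), (True, True, False), (True, True, True)])
    def test_allele_flip_invariance(self, method, flip_mask):
        flipped = [
            InstrumentSummary(i.snp_id, -i.beta_x, i.se_x, -i.beta_y, i.se_y) if f else i
            for i, f in zip(THREE, flip_mask)
        ]
        fn = {"ivw": ivw_estimate, "ml": ml_estimate}[method]
        a, b = fn(THREE), fn(flipped)
        assert b.theta == pytest.approx(a.theta, rel=1e-9)
        assert b.se == pytest.approx(a.se, rel=1e-6)

    @pytest.mark.parametrize("method", ["ivw", "ml"])
    def test_outcome_scale_equivariance(self, method):
        c = 37.5
        scaled = [
            InstrumentSummary(i.snp_id, i.beta_x, i.se_x, c * i.beta_y, c * i.se_y)
            for i in THREE
        ]
        fn = {"ivw": ivw_estimate, "ml": ml_estimate}[method]
        a, b = fn(THREE), fn(scaled)
        assert b.theta == pytest.approx(c * a.theta, rel=1e-8)
        assert b.se == pytest.approx(c * a.se, rel=1e-5)

    def test_se_shrinks_with_instrument_strength(self):
        """se(theta) is monotone decreasing in sum(beta_x^2/se_y^2)."""
        ses = []
        for scale in (1.0, 2.0, 4.0, 8.0):
            insts = [
                InstrumentSummary(i.snp_id, scale * i.beta_x, i.se_x, scale * i.beta_y, i.se_y)
                for i in THREE
            ]
            ses.append(ivw_estimate(insts).se)
        assert all(a > b for a, b in zip(ses, ses[1:]))

    @given(st.floats(0.05, 5.0), st.floats(-3.0, 3.0))
    @settings(deadline=None, max_examples=30)
    def test_ivw_wald_consistency_property(self, bx, ratio):
        inst = InstrumentSummary("s", bx, 0.1, ratio * bx, 0.2)
        assert ivw_estimate([inst]).theta == pytest.approx(ratio, rel=1e-9, abs=1e-9)
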