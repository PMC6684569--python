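"""Partial correlation, FDR, normality checks, and mediation inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from oracles import brute_bh_flags

from connlife.exceptions import (
    DegenerateInputError,
    ParameterError,
    UndefinedStatisticError,
)
from connlife.inference import (
    Mediation,
    bh_fdr,
    bootstrap_mediation,
    fit_mediation,
    ks_normality,
    mediation_candidates,
    partial_correlation,
)


class TestPartialCorrelation:
    def test_without_covariates_equals_pearson(self, rng):
        x, y = rng.normal(size=(2, 60))
        res = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)
        assert res.df == 58

    def test_identical_variables_give_unit_correlation(self, rng):
        x = rng.normal(size=50)
        cov = rng.normal(size=50)
        res = partial_correlation(x, x, covariates=cov)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_confounder_driven_association_vanishes_partially(self, rng):
        n = 400
        z = rng.normal(size=n)
        x = z + 0.3 * rng.normal(size=n)
        y = z + 0.3 * rng.normal(size=n)
        marginal = partial_correlation(x, y)
        partial = partial_correlation(x, y, covariates=z)
        assert marginal.r > 0.7
        assert abs(partial.r) < 0.15

    def test_residual_and_regression_coefficient_routes_agree(self, rng):
        """Partial r via residualization must match the t-statistic route
        from the multiple regression of y on [x, covariates]."""
        n = 120
        C = rng.normal(size=(n, 2))
        x = rng.normal(size=n) + C @ [0.5, -0.2]
        y = 0.3 * x + C @ [0.2, 0.4] + rng.normal(size=n)
        res = partial_correlation(x, y, covariates=C)
        X = np.column_stack([np.ones(n), x, C])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = n - X.shape[1]
        sigma2 = resid @ resid / df
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        r_from_t = np.sign(t) * np.sqrt(t**2 / (t**2 + df))
        assert res.r == pytest.approx(r_from_t, abs=1e-10)

    def test_agrees_with_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 80
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "c": rng.normal(size=n),
            }
        )
        df["y"] += 0.4 * df["x"] + 0.5 * df["c"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c"])
        res = partial_correlation(df["x"], df["y"], covariates=df[["c"]])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_degenerate_inputs_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(UndefinedStatisticError):
            partial_correlation(x, np.full(30, 2.0))
        with pytest.raises(ParameterError):
            partial_correlation([1.0, 2.0], [3.0, 4.0])


class TestBhFdr:
    def test_stepup_rule_hand_example(self):
        flags = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert flags.all()  # p_(4) = 0.04 <= 4 * 0.05 / 4

    def test_all_ones_none_significant(self):
        assert not bh_fdr([1.0, 1.0, 1.0]).any()

    def test_single_test_reduces_to_plain_threshold(self):
        assert bh_fdr([0.04], q=0.05).all()
        assert not bh_fdr([0.06], q=0.05).any()

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        arrays(
            np.float64,
            st.integers(1, 30),
            elements=st.floats(0, 1, allow_nan=False),
        ),
        st.floats(0.01, 0.2),
    )
    def test_matches_brute_force_definition(self, p, q):
        assert np.array_equal(bh_fdr(p, q), brute_bh_flags(p, q))


class TestKsNormality:
    def test_normal_samples_rarely_rejected(self):
        rejections = 0
        for seed in range(50):
            v = np.random.default_rng(seed).normal(2.0, 3.0, size=500)
            _, _, reject = ks_normality(v)
            rejections += reject
        assert rejections <= 5  # calibrated: <= 10% of 50 seeds

    def test_uniform_sample_rejected(self):
        v = np.random.default_rng(0).uniform(size=500)
        stat, p, reject = ks_normality(v)
        assert reject and p < 0.05

    def test_minimum_sample_size_and_zero_variance(self):
        with pytest.raises(ParameterError):
            ks_normality([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(DegenerateInputError):
            ks_normality(np.full(10, 3.0))


class TestMediationPointEstimates:
    def test_mediator_independent_of_x_gives_zero_indirect_effect(self, rng):
        n = 60
        x = rng.normal(size=n)
        m = rng.normal(size=n)  # a != 0 only by sampling noise
        y = m.copy()  # b = 1 exactly, no noise
        res = fit_mediation(x, m, y)
        assert res.b == pytest.approx(1.0, abs=1e-12)
        assert res.ab == pytest.approx(res.a, abs=1e-12)
        assert abs(res.a) < 0.5  # only sampling noise links x and m

    def test_indirect_effect_identity_on_arbitrary_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(15, 80))
            x = rng.normal(size=n)
            m = rng.normal(size=n)
            y = rng.normal(size=n)
            C = rng.normal(size=(n, int(rng.integers(0, 3))))
            res = fit_mediation(x, m, y, C if C.shape[1] else None)
            assert res.ab == pytest.approx(res.c - res.c_prime, abs=1e-10)

    def test_matches_statsmodels_ols_coefficients(self, rng):
        import statsmodels.api as sm

        n = 90
        x = rng.normal(size=n)
        c = rng.normal(size=n)
        m = -0.5 * x + 0.2 * c + rng.normal(size=n)
        y = 0.4 * m - 0.1 * x + rng.normal(size=n)
        res = fit_mediation(x, m, y, covariates=c)
        Xa = sm.add_constant(np.column_stack([x, c]))
        a_ref = sm.OLS(m, Xa).fit().params[1]
        Xb = sm.add_constant(np.column_stack([m, x, c]))
        fit_b = sm.OLS(y, Xb).fit().params
        assert res.a == pytest.approx(a_ref, abs=1e-10)
        assert res.b == pytest.approx(fit_b[1], abs=1e-10)
        assert res.c_prime == pytest.approx(fit_b[2], abs=1e-10)


class TestBootstrapMediation:
    def _planted(self, rng, n=500, a=-0.5, b=0.4):
        x = rng.normal(size=n)
        cov = (rng.random(n) < 0.7).astype(float)
        m = a * x + 0.1 * cov + 0.3 * rng.normal(size=n)
        y = b * m - 0.2 * x + 0.2 * cov + 0.3 * rng.normal(size=n)
        return x, m, y, cov

    def test_planted_paths_covered_by_bootstrap_interval(self, rng):
        x, m, y, cov = self._planted(rng)
        est = Mediation(n_boot=2000, seed=1).fit(x, m, y, cov)
        lo, hi = est.conf_int("ab")
        assert lo <= -0.5 * 0.4 <= hi
        assert est.p_per_path_["ab"] < 0.01
        assert est.z_per_path_["ab"] < 0

    def test_identity_holds_on_every_bootstrap_draw(self, rng):
        x, m, y, cov = self._planted(rng, n=80)
        est = Mediation(n_boot=500, seed=2).fit(x, m, y, cov)
        boots = est.boot_paths_
        ab, c, c_prime = boots[:, 4], boots[:, 3], boots[:, 2]
        assert np.allclose(ab, c - c_prime, atol=1e-10)

    def test_fixed_seed_reproduces_z_and_p(self, rng):
        x, m, y, cov = self._planted(rng, n=100)
        r1 = bootstrap_mediation(x, m, y, cov, n_boot=800, seed=9)
        r2 = bootstrap_mediation(x, m, y, cov, n_boot=800, seed=9)
        assert r1.z_per_path == r2.z_per_path
        assert r1.p_per_path == r2.p_per_path

    def test_p_value_floor_is_two_over_n_boot(self, rng):
        x, m, y, cov = self._planted(rng, n=800)
        res = bootstrap_mediation(x, m, y, cov, n_boot=1000, seed=3)
        assert res.p_per_path["a"] >= 2 / 1000

    def test_strong_mediation_detected_in_most_simulations(self):
        detections = 0
        n_sims = 20
        for seed in range(n_sims):
            rng = np.random.default_rng(1000 + seed)
            x, m, y, cov = self._planted(rng, n=150)
            res = bootstrap_mediation(x, m, y, cov, n_boot=500, seed=seed)
            detections += res.p_per_path["ab"] < 0.05
        assert detections >= int(0.8 * n_sims)

    def test_percentile_and_bca_intervals_both_cover_truth(self, rng):
        x, m, y, cov = self._planted(rng, n=300)
        for method in ("percentile", "bca"):
            est = Mediation(n_boot=1000, seed=4, ci_method=method).fit(x, m, y, cov)
            lo, hi = est.conf_int("ab")
            assert lo < -0.2 < hi


def test_mediation_candidate_rule_requires_both_associations(rng):
    import pandas as pd

    n = 200
    age = rng.uniform(21, 86, size=n)
    sex = (rng.random(n) < 0.7).astype(float)
    linked = -0.01 * age + 0.1 * rng.normal(size=n)
    unlinked = rng.normal(size=n)
    ace = 95 + 30 * linked - 0.02 * age + rng.normal(size=n)
    measures = pd.DataFrame({"linked": linked, "unlinked": unlinked})
    assert mediation_candidates(measures, age, ace, sex) == ["linked"]
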