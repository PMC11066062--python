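"""NB-GLM fitting, Wald inference, BH adjustment, and contrast recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from imnatac.differential import (
    bh_adjust,
    build_design,
    fit_nb_glm,
    run_differential,
    wald_test,
)
from imnatac.io import CountsMatrix


def _nb(rng, mu, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestFitNbGlm:
    def test_two_group_fit_recovers_group_means(self):
        # For the saturated two-group model the NB score equations force the
        # fitted means to equal the arithmetic group means.
        rng = np.random.default_rng(1)
        y0 = _nb(rng, 100, 0.1, 40)
        y1 = _nb(rng, 220, 0.1, 40)
        y = np.concatenate([y0, y1])
        X = np.column_stack([np.ones(80), np.r_[np.zeros(40), np.ones(40)]])
        beta, cov = fit_nb_glm(y, X, np.ones(80), alpha=0.1)
        np.testing.assert_allclose(np.exp(beta[0]), y0.mean(), rtol=1e-6)
        np.testing.assert_allclose(np.exp(beta[0] + beta[1]), y1.mean(), rtol=1e-6)
        assert np.isclose(beta[1], np.log(y1.mean() / y0.mean()), rtol=1e-6)

    def test_alpha_zero_matches_poisson_oracle(self):
        rng = np.random.default_rng(2)
        n = 120
        x = rng.normal(size=n)
        g = rng.integers(0, 2, size=n).astype(float)
        mu = np.exp(3 + 0.4 * x - 0.6 * g)
        y = rng.poisson(mu)
        X = np.column_stack([np.ones(n), x, g])
        beta, _ = fit_nb_glm(y, X, np.ones(n), alpha=0.0)
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(beta, oracle.params, atol=1e-6)

    def test_offset_handling_matches_poisson_oracle(self):
        rng = np.random.default_rng(3)
        n = 100
        s = rng.uniform(0.5, 2.0, size=n)
        g = rng.integers(0, 2, size=n).astype(float)
        y = rng.poisson(s * np.exp(4 + 0.5 * g))
        X = np.column_stack([np.ones(n), g])
        beta, _ = fit_nb_glm(y, X, s, alpha=0.0)
        oracle = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(s)).fit()
        np.testing.assert_allclose(beta, oracle.params, atol=1e-6)

    def test_all_zero_row_flagged_by_caller(self):
        # an all-zero group produces separation; the fit must not raise
        y = np.r_[np.zeros(20), np.random.default_rng(4).poisson(50, 20)]
        X = np.column_stack([np.ones(40), np.r_[np.zeros(20), np.ones(20)]])
        beta, cov = fit_nb_glm(y, X, np.ones(40), alpha=0.05)
        assert beta.shape == (2,)  # either damped estimate or NaN flag, no exception


class TestWald:
    def test_zero_beta_gives_p_one(self):
        z, p = wald_test(0.0, 1.0)
        assert z == 0.0 and p == 1.0

    def test_quantile_at_005(self):
        _, p = wald_test(1.959964, 1.0)
        assert abs(p - 0.05) < 1e-6

    def test_sign_and_se_validation(self):
        z, _ = wald_test(-2.0, 0.5)
        assert z == -4.0
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestBH:
    def _oracle(self, p):
        # independent step-up implementation, straight from the definition
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        q = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(q, 1.0)
        return out

    def test_worked_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), self._oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


def _cohort(rng, n0=60, n1=60, n_regions=300, planted=None, alpha0=0.02, a1=2.0):
    """Two-group NB cohort; ``planted`` maps region index -> log2fc."""
    planted = planted or {}
    n = n0 + n1
    group = np.r_[np.zeros(n0), np.ones(n1)]
    s = np.exp(rng.uniform(-0.3, 0.3, size=n))
    mus = np.exp(rng.uniform(np.log(50), np.log(800), size=n_regions))
    counts = np.empty((n_regions, n), dtype=np.int64)
    for i in range(n_regions):
        lfc = planted.get(i, 0.0)
        mu = mus[i] * 2.0 ** (lfc * group)
        alpha = a1 / mus[i] + alpha0
        r = 1.0 / alpha
        counts[i] = rng.negative_binomial(r, r / (r + mu * s))
    cm = CountsMatrix(counts, [f"r{i}" for i in range(n_regions)], [f"s{j}" for j in range(n)])
    table = pd.DataFrame(
        {
            "sample_id": cm.sample_ids,
            "group": np.where(group == 1, "B", "A"),
            "frip": rng.uniform(0.2, 0.3, size=n),
        }
    )
    return cm, table


class TestRunDifferential:
    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(10)
        cm, table = _cohort(rng, n_regions=800)
        # permute labels: no region is truly differential
        table["group"] = rng.permutation(table["group"].to_numpy())
        res = run_differential(cm, table, contrast="group", covariates=["frip"])
        frac = np.mean(res.table["p"].dropna() < 0.05)
        assert 0.03 < frac < 0.07

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(11)
        planted = {i: -0.6 for i in range(8)}
        cm, table = _cohort(rng, n0=112, n1=27, n_regions=200, planted=planted)
        res = run_differential(cm, table, contrast="group", covariates=["frip"])
        est = res.table.loc[:7, "log2fc"].mean()
        assert abs(est - (-0.6)) < 0.1

    def test_dar_set_equals_planted_at_thresholds(self):
        rng = np.random.default_rng(12)
        planted = {i: 1.6 * (-1) ** i for i in range(6)}
        cm, table = _cohort(rng, n_regions=250, planted=planted)
        res = run_differential(
            cm, table, contrast="group", adj_p_threshold=0.01, min_abs_log2fc=0.5
        )
        assert set(res.dar_ids) == {f"r{i}" for i in range(6)}

    def test_single_level_contrast_rejected(self):
        rng = np.random.default_rng(13)
        cm, table = _cohort(rng, n_regions=20)
        table["group"] = "A"
        with pytest.raises(ValueError):
            run_differential(cm, table, contrast="group")

    def test_log2fc_sign_convention(self):
        # contrast level "B" (non-reference, alphabetical coding) higher ->
        # positive log2fc
        rng = np.random.default_rng(14)
        cm, table = _cohort(rng, n_regions=60, planted={0: 2.0})
        res = run_differential(cm, table, contrast="group")
        assert res.table.loc[0, "log2fc"] > 1.0
        assert res.contrast_column == "group[B]"


class TestDesign:
    def test_missing_rows_dropped(self):
        table = pd.DataFrame(
            {
                "sample_id": list("abcd"),
                "group": ["A", "B", None, "B"],
                "frip": [0.2, 0.3, 0.25, 0.22],
            }
        )
        d = build_design(table, "group", ["frip"])
        assert d.sample_ids == ["a", "b", "d"]
        assert d.columns == ["intercept", "frip", "group[B]"]

    def test_rank_deficiency_detected(self):
        table = pd.DataFrame(
            {
                "sample_id": list("abcd"),
                "group": ["A", "A", "B", "B"],
                "dup": ["X", "X", "Y", "Y"],  # aliases the contrast
            }
        )
        with pytest.raises(ValueError, match="rank"):
            build_design(table, "group", ["dup"])
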