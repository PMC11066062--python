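"""Staged predictor filters, split, stability selection, and evaluation."""

import numpy as np
import pandas as pd
import pytest

from imnatac.io import TransformedMatrix
from imnatac.progression import (
    FilterReport,
    batch_filter,
    correlation_outlier_filter,
    iqr_outlier_filter,
    refit_ols_and_evaluate,
    run_progression,
    stability_selection,
    subset_tss_regions,
    train_test_split_stratified,
)
from imnatac.regions import GeneRecord, GenomicRegion, RegionSet


def _tm(values, sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return TransformedMatrix(
        values,
        [f"r{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
    )


class TestSubsetTss:
    GENES = [GeneRecord("g", "chr1", 100_000, "+")]

    def _matrix_with_regions(self, centers):
        regions = RegionSet(
            [GenomicRegion("chr1", c - 400, c + 400, f"r{i}") for i, c in enumerate(centers)]
        )
        tm = _tm(np.zeros((len(centers), 4)))
        return tm, regions

    def test_2kb_boundary(self):
        tm, regions = self._matrix_with_regions([101_999, 102_001, 98_001])
        out = subset_tss_regions(tm, regions, self.GENES, halfwidth=2000)
        assert out.region_ids == ["r0", "r2"]  # 1,999 bp kept; 2,001 bp dropped

    def test_chromosome_without_genes_dropped(self):
        regions = RegionSet(
            [
                GenomicRegion("chr1", 99_600, 100_400, "r0"),
                GenomicRegion("chr2", 99_600, 100_400, "r1"),
            ]
        )
        tm = _tm(np.zeros((2, 4)))
        out = subset_tss_regions(tm, regions, self.GENES, halfwidth=2000)
        assert out.region_ids == ["r0"]

    def test_empty_result_is_an_error(self):
        tm, regions = self._matrix_with_regions([500_000])
        with pytest.raises(ValueError):
            subset_tss_regions(tm, regions, self.GENES, halfwidth=2000)


class TestCorrelationFilter:
    def _cohort(self, rng, n_good=50, n_bad=5, n_regions=300):
        profile = rng.normal(0, 2, size=n_regions)
        good = profile[:, None] + rng.normal(0, 0.3, size=(n_regions, n_good))
        bad = rng.normal(0, 2, size=(n_regions, n_bad))  # no shared profile
        return _tm(np.hstack([good, bad]))

    def test_planted_decorrelated_samples_flagged_exactly(self):
        rng = np.random.default_rng(0)
        tm = self._cohort(rng)
        excluded = correlation_outlier_filter(tm)
        assert sorted(excluded) == [f"s{j}" for j in range(50, 55)]

    def test_homogeneous_cohort_excludes_nothing(self):
        rng = np.random.default_rng(1)
        tm = self._cohort(rng, n_good=40, n_bad=0)
        assert correlation_outlier_filter(tm) == []

    def test_two_equal_halves_protected_by_size_guard(self):
        rng = np.random.default_rng(2)
        p1 = rng.normal(0, 2, size=200)
        p2 = rng.normal(0, 2, size=200)
        a = p1[:, None] + rng.normal(0, 0.3, size=(200, 20))
        b = p2[:, None] + rng.normal(0, 0.3, size=(200, 20))
        tm = _tm(np.hstack([a, b]))
        assert correlation_outlier_filter(tm) == []

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_outlier_filter(_tm(np.zeros((10, 5))))


class TestIqrFilter:
    def test_worked_five_value_example(self):
        # type-7 quartiles of (-5, -0.4, -0.3, -0.2, -0.1): Q1 = -0.4,
        # Q3 = -0.2, IQR = 0.2, fences (-0.7, 0.1) -> only -5 is out.
        slopes = pd.Series([-5.0, -0.4, -0.3, -0.2, -0.1], index=list("abcde"))
        assert iqr_outlier_filter(slopes) == ["a"]

    def test_tight_symmetric_slopes_kept(self):
        slopes = pd.Series([-0.5, -0.45, -0.4, -0.35, -0.3], index=list("abcde"))
        assert iqr_outlier_filter(slopes) == []

    def test_requires_four_values(self):
        with pytest.raises(ValueError):
            iqr_outlier_filter(pd.Series([1.0, 2.0, 3.0]))

    def test_missing_values_ignored(self):
        slopes = pd.Series([-5.0, -0.4, -0.3, -0.2, -0.1, np.nan], index=list("abcdef"))
        assert iqr_outlier_filter(slopes) == ["a"]


class TestBatchFilter:
    def _table(self, sizes):
        rows = []
        for b, size in enumerate(sizes):
            rows += [{"sample_id": f"b{b}_{i}", "diff_batch": f"b{b}"} for i in range(size)]
        return pd.DataFrame(rows)

    def test_small_batches_removed(self):
        out = batch_filter(self._table([10, 4, 3]), min_per_batch=4)
        assert sorted(out) == [f"b2_{i}" for i in range(3)]

    def test_all_batches_large_enough(self):
        assert batch_filter(self._table([4, 5]), min_per_batch=4) == []

    def test_min_one_keeps_everything(self):
        assert batch_filter(self._table([1, 2]), min_per_batch=1) == []


class TestSplit:
    def test_split_sizes_and_stratification(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(156)],
                "diff_batch": np.repeat([f"b{k}" for k in range(13)], 12),
            }
        )
        train, test = train_test_split_stratified(table, test_fraction=0.1, seed=7)
        assert len(train) == 140 and len(test) == 16
        assert set(train) | set(test) == set(table["sample_id"])
        per_batch = table.set_index("sample_id").loc[test, "diff_batch"].value_counts()
        assert per_batch.max() <= 2  # spread across batches

    def test_deterministic_under_seed(self):
        table = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(30)], "diff_batch": ["b"] * 30}
        )
        a = train_test_split_stratified(table, seed=5)
        b = train_test_split_stratified(table, seed=5)
        assert a == b


class TestRefitAndEvaluate:
    def test_perfect_linear_fit(self):
        X = np.arange(10.0)[:, None]
        y = 2.0 * X[:, 0] - 1.0
        model, m = refit_ols_and_evaluate(X, y, X, y, ["r0"])
        assert m["test_rmse"] == pytest.approx(0.0, abs=1e-10)
        assert m["test_r2"] == pytest.approx(1.0)

    def test_four_point_toy_train_mean_convention(self):
        # training fixes yhat = x and ybar_train = 2; on the test points the
        # predictions are (1,2,3,5) vs truth (1,2,3,4): RMSE = 0.5 and
        # R^2 = 1 - 1/6 under the train-mean anchoring.
        X_train = np.array([[1.0], [2.0], [3.0]])
        y_train = np.array([1.0, 2.0, 3.0])
        X_test = np.array([[1.0], [2.0], [3.0], [5.0]])
        y_test = np.array([1.0, 2.0, 3.0, 4.0])
        _, m = refit_ols_and_evaluate(X_train, y_train, X_test, y_test, ["r0"])
        assert m["test_rmse"] == pytest.approx(0.5)
        assert m["test_r2"] == pytest.approx(1.0 - 1.0 / 6.0)

    def test_constant_predictor_scores_zero(self):
        rng = np.random.default_rng(4)
        X_train = rng.normal(size=(20, 1)) * 0  # zero predictor -> intercept = ybar
        y_train = rng.normal(size=20)
        X_test = np.zeros((10, 1))
        y_test = rng.normal(size=10)
        with pytest.warns(UserWarning, match="rank"):
            _, m = refit_ols_and_evaluate(X_train, y_train, X_test, y_test, ["r0"])
        assert m["test_r2"] == pytest.approx(0.0, abs=1e-10)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            refit_ols_and_evaluate(np.zeros((5, 0)), np.zeros(5), np.zeros(2, ), np.zeros(2), [])


class TestStability:
    def test_deterministic_under_master_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 40))
        y = X[:, 0] * 1.5 + rng.normal(0, 0.3, 60)
        ids = [f"r{i}" for i in range(40)]
        a = stability_selection(X, y, ids, n_runs=5, master_seed=9)
        b = stability_selection(X, y, ids, n_runs=5, master_seed=9)
        assert [r.selected_region_ids for r in a.runs] == [r.selected_region_ids for r in b.runs]
        assert a.majority_set == b.majority_set

    def test_noise_only_majority_near_empty(self):
        # on a fixed pure-noise dataset the strongest chance correlation is a
        # real (if spurious) feature of that dataset and may recur across
        # fold reassignments, so the majority set is near-empty, not
        # necessarily empty
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 60))
        y = rng.normal(size=80)
        res = stability_selection(X, y, [f"r{i}" for i in range(60)], n_runs=10, master_seed=3)
        assert len(res.majority_set) <= 3

    def test_strong_predictor_always_selected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 50))
        y = 2.0 * X[:, 7] + rng.normal(0, 0.2, 80)
        res = stability_selection(
            X, y, [f"r{i}" for i in range(50)], X_test=X, y_test=y, n_runs=10, master_seed=4
        )
        assert "r7" in res.majority_set
        assert res.selection_frequency["r7"] == 1.0
        agg = res.aggregate()
        assert agg["train_r2_mean"] > 0.9

    def test_filter_report_invariants(self):
        rep = FilterReport(["a"], ["b"], ["c"], ["d", "e"])
        assert rep.accounts_for(list("abcde"))
        assert not rep.accounts_for(list("abcdef"))
        with pytest.raises(ValueError):
            FilterReport(["a"], ["a"], [], ["b"])


class TestEndToEnd:
    def test_filter_chain_recovers_planted_pathologies(self, tiny_normalized):
        cohort, tm = tiny_normalized
        res = run_progression(
            tm,
            cohort.metadata,
            cohort.regions,
            cohort.genes,
            n_runs=4,
            master_seed=2,
        )
        truth = cohort.truth
        assert set(truth.corr_outlier_ids) <= set(res.filter_report.excluded_by_correlation)
        assert set(truth.iqr_outlier_ids) <= set(res.filter_report.excluded_by_slope_iqr)
        assert set(truth.small_batch_ids) <= set(res.filter_report.excluded_by_batch)
        n_eligible = (
            cohort.metadata["alsfrs_r_slope"].notna()
            & (cohort.metadata["case_status"] == "ALS")
        ).sum()
        assert res.filter_report.accounts_for(
            cohort.metadata.loc[
                cohort.metadata["alsfrs_r_slope"].notna()
                & (cohort.metadata["case_status"] == "ALS"),
                "sample_id",
            ].tolist()
        )
        assert len(res.train_ids) + len(res.test_ids) == len(res.filter_report.retained)
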