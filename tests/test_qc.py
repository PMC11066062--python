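"""Variable-region selection, PCA, label imputation, RniP, correlation clustering."""

import numpy as np
import pandas as pd
import pytest

from imnatac.io import TransformedMatrix
from imnatac.qc import (
    chrx_rnip,
    impute_pbmc_labels,
    inter_sample_correlation_cluster,
    pca,
    top_variable_regions,
)


def _tm(values):
    values = np.asarray(values, dtype=float)
    return TransformedMatrix(
        values,
        [f"r{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )


class TestTopVariableRegions:
    def test_high_variance_region_ranked_first(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 10))
        vals[7] *= 50
        assert top_variable_regions(_tm(vals), 1) == ["r7"]

    def test_n_equals_all_returns_identity_set(self):
        rng = np.random.default_rng(1)
        tm = _tm(rng.normal(size=(5, 6)))
        assert sorted(top_variable_regions(tm, 5)) == sorted(tm.region_ids)

    def test_ties_break_by_region_id(self):
        vals = np.tile(np.array([[0.0, 1.0, 2.0]]), (4, 1))
        assert top_variable_regions(_tm(vals), 2) == ["r0", "r1"]

    def test_invalid_n_rejected(self):
        tm = _tm(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            top_variable_regions(tm, 0)
        with pytest.raises(ValueError):
            top_variable_regions(tm, 4)


class TestPca:
    def test_rank_one_structure_dominates(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=30)
        v = rng.normal(size=15)
        vals = np.outer(u, v) * 5 + rng.normal(0, 0.1, size=(30, 15))
        res = pca(_tm(vals))
        assert res.variance_fractions[0] >= 0.9

    def test_scores_invariant_to_per_region_constants(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(12, 8))
        a = pca(_tm(vals))
        b = pca(_tm(vals + rng.normal(size=(12, 1))))  # constant per region
        np.testing.assert_allclose(np.abs(a.scores), np.abs(b.scores), atol=1e-8)

    def test_variance_fractions_sorted_and_bounded(self):
        rng = np.random.default_rng(4)
        res = pca(_tm(rng.normal(size=(25, 10))))
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)
        assert res.variance_fractions.sum() <= 1 + 1e-9

    def test_sex_separation_on_synthetic_cohort(self, tiny_normalized):
        # sex structure (chrY/X-escape regions) separates samples in PC space
        cohort, tm = tiny_normalized
        top = top_variable_regions(tm, 20)
        res = pca(tm, top, n_components=2)
        sex = cohort.metadata.set_index("sample_id")["sex"].reindex(res.scores.index)
        best = 0.0
        for pc in ["PC1", "PC2"]:
            f = res.scores.loc[sex == "Female", pc]
            m = res.scores.loc[sex == "Male", pc]
            thr = (f.mean() + m.mean()) / 2
            acc = max(
                ((f > thr).sum() + (m <= thr).sum()) / len(sex),
                ((f <= thr).sum() + (m > thr).sum()) / len(sex),
            )
            best = max(best, acc)
        assert best >= 0.9

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(_tm(np.ones((5, 5))))


class TestImputePbmc:
    def test_hidden_labels_recovered_in_planted_clusters(self):
        # two clean source-cell clusters in region space; a hidden sample
        # inside a cluster must take that cluster's label
        rng = np.random.default_rng(5)
        n_per, n_regions = 20, 60
        shift = np.zeros(n_regions)
        shift[:15] = 3.0  # T-cell-depleted block
        a = rng.normal(0, 0.5, size=(n_regions, n_per))
        b = shift[:, None] + rng.normal(0, 0.5, size=(n_regions, n_per))
        tm = _tm(np.hstack([a, b]))
        labels = ["T-cell"] * n_per + ["non-T-cell"] * n_per
        meta = pd.DataFrame({"sample_id": tm.sample_ids, "pbmc_type": labels})
        hide = ["s2", "s5", "s25", "s33"]
        truth = meta.set_index("sample_id").loc[hide, "pbmc_type"].copy()
        meta.loc[meta["sample_id"].isin(hide), "pbmc_type"] = np.nan
        completed = impute_pbmc_labels(tm, meta, k=5)
        assert (completed[hide].to_numpy() == truth.to_numpy()).all()

    def test_no_missing_labels_is_identity(self, tiny_normalized):
        cohort, tm = tiny_normalized
        meta = cohort.metadata.copy()
        meta["pbmc_type"] = meta["pbmc_type"].fillna("T-cell")
        completed = impute_pbmc_labels(tm, meta, k=5)
        assert (completed.to_numpy() == meta.set_index("sample_id")["pbmc_type"].reindex(completed.index).to_numpy()).all()

    def test_too_few_labeled_rejected(self, tiny_normalized):
        cohort, tm = tiny_normalized
        meta = cohort.metadata.copy()
        meta["pbmc_type"] = pd.Series(np.nan, index=meta.index, dtype=object)
        meta.loc[meta.index[:3], "pbmc_type"] = "T-cell"
        with pytest.raises(ValueError):
            impute_pbmc_labels(tm, meta, k=15)


class TestRnip:
    def _table(self, rows):
        df = pd.DataFrame(rows)
        df["sample_id"] = [f"s{i}" for i in range(len(df))]
        return df

    def test_worked_arithmetic(self):
        t = self._table(
            [
                {"sex": "Female", "total_reads": 10_000, "chrx_reads": 1_000, "chrx_reads_in_peaks": 400},
                {"sex": "Male", "total_reads": 10_000, "chrx_reads": 400, "chrx_reads_in_peaks": 400},
            ]
        )
        res = chrx_rnip(t)
        np.testing.assert_allclose(res.per_sample["rnip_normalized"], [0.06, 0.0])

    def test_scale_consistency(self):
        t1 = self._table(
            [{"sex": "Male", "total_reads": 10_000, "chrx_reads": 1_000, "chrx_reads_in_peaks": 300}]
        )
        t2 = self._table(
            [{"sex": "Male", "total_reads": 20_000, "chrx_reads": 2_000, "chrx_reads_in_peaks": 600}]
        )
        assert (
            chrx_rnip(t1).per_sample["rnip_normalized"].iloc[0]
            == chrx_rnip(t2).per_sample["rnip_normalized"].iloc[0]
        )

    def test_invalid_counts_rejected(self):
        t = self._table(
            [{"sex": "Male", "total_reads": 100, "chrx_reads": 10, "chrx_reads_in_peaks": 20}]
        )
        with pytest.raises(ValueError):
            chrx_rnip(t)

    def test_planted_female_male_ratio_recovered(self, tiny_cohort):
        res = chrx_rnip(tiny_cohort.metadata)
        ratio = res.group_medians["Female"] / res.group_medians["Male"]
        planted = tiny_cohort.config.rnip_female_ratio
        assert abs(ratio - planted) / planted < 0.15


class TestCorrelationCluster:
    def test_identical_samples_single_cluster(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=50)
        vals = np.column_stack([base + rng.normal(0, 1e-6, 50) for _ in range(3)])
        res = inter_sample_correlation_cluster(
            TransformedMatrix(vals, [f"r{i}" for i in range(50)], ["a", "b", "c"])
        )
        assert np.all(res.correlation > 0.999)
        assert res.flagged_sample_ids == []

    def test_planted_outlier_block_flagged(self):
        rng = np.random.default_rng(7)
        profile = rng.normal(0, 2, 300)
        good = profile[:, None] + rng.normal(0, 0.3, (300, 30))
        bad = rng.normal(0, 2, (300, 3))
        tm = _tm(np.hstack([good, bad]))
        res = inter_sample_correlation_cluster(tm)
        assert sorted(res.flagged_sample_ids) == ["s30", "s31", "s32"]

    def test_dendrogram_heights_non_decreasing(self):
        rng = np.random.default_rng(8)
        tm = _tm(rng.normal(size=(40, 12)))
        res = inter_sample_correlation_cluster(tm)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            inter_sample_correlation_cluster(_tm(np.zeros((5, 2))))
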