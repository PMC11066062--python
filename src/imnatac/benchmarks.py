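"""Recovery and calibration experiments on the synthetic cohort.

Each function runs one self-contained experiment — generating its inputs
from a seed, running the corresponding analysis, and measuring recovery or
calibration against the planted ground truth — and returns a flat dict of
named quantities.  The experiments double as the package's acceptance
checks: the test suite asserts on them and ``scripts/acceptance.py``
reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rand import child_seed, stream
from .coexpression import association_test, map_all_pairs
from .differential import run_differential
from .io import CountsMatrix
from .lasso import StandardizedProblem, lasso_fit, lambda_max
from .normalization import (
    estimate_dispersions,
    size_factors_median_of_ratios,
    vst,
)
from .progression import iqr_outlier_filter, run_progression
from .qc import chrx_rnip, guarded_correlation_split, impute_pbmc_labels
from .regions import GenomicRegion, RegionSet, build_consensus
from .simulate import CohortConfig, simulate_cohort
from .varpart import VarParSpec, partition_variance

__all__ = [
    "lasso_correctness",
    "progression_recovery",
    "differential_calibration",
    "confounding_demonstration",
    "normalization_checks",
    "varpart_checks",
    "coexpression_checks",
    "qc_checks",
]


# ---------------------------------------------------------------------------
# 1. LASSO correctness: KKT bound, OLS limit, orthonormal closed form


def lasso_correctness(seed: int = 0) -> dict:
    rng = stream(seed, "lasso")
    n, p = 80, 20
    X = rng.normal(size=(n, p))
    y = X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.5, n)

    lmax = lambda_max(X, y)
    _, b_at_max = lasso_fit(X, y, lmax)
    kkt_nonzero_at_lambda_max = int(np.count_nonzero(b_at_max))
    _, b_below = lasso_fit(X, y, lmax * 0.99)
    nonzero_just_below = int(np.count_nonzero(b_below))

    b0, b = lasso_fit(X, y, 0.0, tol=1e-10)
    A = np.column_stack([np.ones(n), X])
    ols = np.linalg.lstsq(A, y, rcond=None)[0]
    ols_max_abs_diff = float(np.max(np.abs(np.r_[b0, b] - ols)))

    # orthonormal standardized design (centered before QR, so columns stay
    # centered with unit sd): the solution is the exact soft threshold
    A2 = rng.normal(size=(200, 12))
    A2 -= A2.mean(axis=0)
    Q, _ = np.linalg.qr(A2)
    Xo = Q * np.sqrt(200)
    yo = rng.normal(size=200)
    yo -= yo.mean()
    prob = StandardizedProblem.from_data(Xo, yo)
    lam = 0.04
    beta = prob.solve(lam, tol=1e-12)
    closed = np.sign(prob.c) * np.maximum(np.abs(prob.c) - lam, 0.0)
    soft_threshold_max_abs_diff = float(np.max(np.abs(beta - closed)))

    return {
        "lasso_nonzero_at_lambda_max": kkt_nonzero_at_lambda_max,
        "lasso_nonzero_just_below_lambda_max": nonzero_just_below,
        "lasso_ols_max_abs_diff": ols_max_abs_diff,
        "lasso_soft_threshold_max_abs_diff": soft_threshold_max_abs_diff,
        "n": n,
    }


# ---------------------------------------------------------------------------
# 2. progression-procedure recovery


def progression_recovery(seed: int = 0, n_runs: int = 100) -> dict:
    cohort = simulate_cohort(CohortConfig(), seed=child_seed(seed, "prog-cohort"))
    counts, truth, meta = cohort.counts, cohort.truth, cohort.metadata
    sf = size_factors_median_of_ratios(counts)
    dm = estimate_dispersions(counts, sf)
    tm = vst(counts, sf, dm)
    res = run_progression(
        tm,
        meta,
        cohort.regions,
        cohort.genes,
        n_runs=n_runs,
        master_seed=child_seed(seed, "prog-stability"),
    )
    maj = set(res.stability.majority_set)
    true = set(truth.driver_region_ids)
    agg = res.stability.aggregate()

    # oracle: the planted signal itself, evaluated on the held-out test set
    # with the train-mean anchoring
    midx = meta.set_index("sample_id")
    y_test = midx.loc[res.test_ids, "alsfrs_r_slope"].to_numpy(dtype=float)
    sig_test = truth.slope_signal[res.test_ids].to_numpy(dtype=float)
    ybar_train = float(midx.loc[res.train_ids, "alsfrs_r_slope"].mean())
    planted_r2_test = float(
        1.0 - np.sum((y_test - sig_test) ** 2) / np.sum((y_test - ybar_train) ** 2)
    )
    rep = res.filter_report
    return {
        "prog_n_retained": len(rep.retained),
        "prog_n_train": len(res.train_ids),
        "prog_n_test": len(res.test_ids),
        "prog_excluded_correlation": len(rep.excluded_by_correlation),
        "prog_excluded_iqr": len(rep.excluded_by_slope_iqr),
        "prog_excluded_batch": len(rep.excluded_by_batch),
        "prog_majority_size": len(maj),
        "prog_majority_precision": float(len(maj & true) / max(len(maj), 1)),
        "prog_majority_recall": float(len(maj & true) / len(true)),
        "prog_support_size_mean": float(agg.get("support_size_mean", np.nan)),
        "prog_support_size_se": float(agg.get("support_size_se", np.nan)),
        "prog_n_nonempty_runs": int(agg["n_nonempty_runs"]),
        "prog_train_r2_mean": float(agg.get("train_r2_mean", np.nan)),
        "prog_test_r2_mean": float(agg.get("test_r2_mean", np.nan)),
        "prog_test_rmse_mean": float(agg.get("test_rmse_mean", np.nan)),
        "prog_planted_r2_test": planted_r2_test,
        "prog_test_r2_abs_error": float(
            abs(agg.get("test_r2_mean", np.nan) - planted_r2_test)
        ),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# 3. differential calibration and recovery


def _qc_passing_cohort(cohort):
    """Drop cohort-wide correlation outliers before model-based analyses.

    Grossly decorrelated samples violate the count model in every region
    (their region profile is unrelated to the cohort's), so — as in any
    real workflow — they are removed by the guarded correlation cut before
    differential testing.
    """
    counts = cohort.counts
    sf = size_factors_median_of_ratios(counts)
    dm = estimate_dispersions(counts, sf)
    tm = vst(counts, sf, dm)
    flagged = {tm.sample_ids[j] for j in guarded_correlation_split(tm.values)}
    keep = [s for s in counts.sample_ids if s not in flagged]
    counts = counts.subset_samples(keep)
    meta = cohort.metadata[cohort.metadata["sample_id"].isin(keep)].reset_index(drop=True)
    sf = size_factors_median_of_ratios(counts)
    dm = estimate_dispersions(counts, sf)
    return counts, meta, sf, dm


def differential_calibration(seed: int = 0) -> dict:
    cohort = simulate_cohort(CohortConfig(), seed=child_seed(seed, "diff-cohort"))
    truth = cohort.truth
    counts, meta, sf, dm = _qc_passing_cohort(cohort)
    covs = ["frip", "sequencer", "sex", "pbmc_type"]

    # permutation null: shuffled case labels make every region null
    rng = stream(seed, "diff-permute")
    permuted = meta.copy()
    permuted["case_status"] = rng.permutation(meta["case_status"].to_numpy())
    null_res = run_differential(
        counts, permuted, "case_status", covs, size_factors=sf, dispersion=dm
    )
    pvals = null_res.table["p"].dropna()
    type_i_05 = float((pvals < 0.05).mean())
    type_i_01 = float((pvals < 0.01).mean())

    # planted C9 effect at the printed group sizes (27 POS vs 112 NEG)
    c9_res = run_differential(
        counts, meta, "c9_status", covs, size_factors=sf, dispersion=dm
    )
    c9_ids = truth.region_ids_of_class("c9")
    est = c9_res.table.set_index("region_id").loc[c9_ids, "log2fc"]
    c9_lfc_mean = float(est.mean())
    planted = float(truth.lfc["c9_status[POS]"][truth.region_table["class"] == "c9"].mean())

    # empirical FDR of the case-status contrast at BH 0.1
    case_res = run_differential(
        counts, meta, "case_status", covs, size_factors=sf, dispersion=dm
    )
    tab = case_res.table.set_index("region_id")
    true_case = set(truth.region_ids_of_class("case_effect"))
    disc = tab[tab["adj_p"] < 0.1]
    n_disc = len(disc)
    false_disc = sum(r not in true_case for r in disc.index)
    fdr = float(false_disc / n_disc) if n_disc else 0.0
    mc_se = float(np.sqrt(0.1 * 0.9 / n_disc)) if n_disc else 0.0

    n_c9 = (meta["c9_status"] == "POS").sum(), (meta["c9_status"] == "NEG").sum()
    return {
        "diff_type_i_error_at_05": type_i_05,
        "diff_type_i_error_at_01": type_i_01,
        "diff_c9_log2fc_mean": c9_lfc_mean,
        "diff_c9_log2fc_planted": planted,
        "diff_c9_log2fc_abs_error": float(abs(c9_lfc_mean - planted)),
        "diff_c9_n_pos": int(n_c9[0]),
        "diff_c9_n_neg": int(n_c9[1]),
        "diff_fdr_at_bh_10": fdr,
        "diff_fdr_bound": float(0.1 + 3 * mc_se),
        "diff_n_discoveries_at_bh_10": int(n_disc),
        "n_regions": counts.n_regions,
    }


# ---------------------------------------------------------------------------
# 4. covariate-confounding demonstration


def confounding_demonstration(seed: int = 0) -> dict:
    cohort = simulate_cohort(CohortConfig(), seed=child_seed(seed, "conf-cohort"))
    counts, meta, sf, dm = _qc_passing_cohort(cohort)

    # a pseudo case label confounded with sex (cases mostly female); every
    # "DAR" for this label is a false positive
    rng = stream(seed, "confound")
    female = (meta["sex"] == "Female").to_numpy()
    p_case = np.where(female, 0.8, 0.2)
    label = np.where(rng.random(len(meta)) < p_case, "pseudoA", "pseudoB")
    table = meta.assign(pseudo_case=label)

    naive = run_differential(
        counts, table, "pseudo_case", ["frip"], size_factors=sf, dispersion=dm
    )
    adjusted = run_differential(
        counts, table, "pseudo_case", ["frip", "sex"], size_factors=sf, dispersion=dm
    )
    return {
        "confound_dars_without_sex_covariate": len(naive.dar_ids),
        "confound_dars_with_sex_covariate": len(adjusted.dar_ids),
        "confound_type_i_with_sex_covariate": float(
            (adjusted.table["p"].dropna() < 0.05).mean()
        ),
        "n_regions": counts.n_regions,
    }


# ---------------------------------------------------------------------------
# 5. normalization


def normalization_checks(seed: int = 0) -> dict:
    rng = stream(seed, "norm")
    # exact size factors on proportional columns
    col = rng.integers(5, 500, size=60)
    cm = CountsMatrix(
        np.column_stack([col, 2 * col]),
        [f"r{i}" for i in range(60)],
        ["a", "b"],
    )
    sf = size_factors_median_of_ratios(cm)
    sf_err = float(np.max(np.abs(sf.s - np.array([1 / np.sqrt(2), np.sqrt(2)]))))

    # dispersion-trend recovery and VST variance flattening on trended NB
    alpha0, a1, n = 0.05, 3.0, 150
    mus = np.exp(rng.uniform(np.log(20), np.log(2000), size=400))
    counts = np.empty((400, n), dtype=np.int64)
    for i, m in enumerate(mus):
        a = a1 / m + alpha0
        r = 1.0 / a
        counts[i] = rng.negative_binomial(r, r / (r + m), size=n)
    cm2 = CountsMatrix(counts, [f"t{i}" for i in range(400)], [f"s{j}" for j in range(n)])
    sf2 = size_factors_median_of_ratios(cm2)
    dm = estimate_dispersions(cm2, sf2)
    alpha0_rel_err = float(abs(dm.alpha0 - alpha0) / alpha0)
    a1_rel_err = float(abs(dm.a1 - a1) / a1)

    tm = vst(cm2, sf2, dm)
    sds = tm.values.std(axis=1)
    order = np.argsort(mus)
    bins = np.array_split(order, 4)
    bin_sd = [float(np.median(sds[b])) for b in bins]
    flatness = float(max(bin_sd) / min(bin_sd))
    return {
        "norm_size_factor_max_abs_error": sf_err,
        "norm_alpha0_rel_error": alpha0_rel_err,
        "norm_a1_rel_error": a1_rel_err,
        "norm_vst_sd_quartile_ratio": flatness,
        "n": n,
    }


# ---------------------------------------------------------------------------
# 6. variance partitioning


def varpart_checks(seed: int = 0) -> dict:
    rng = stream(seed, "varpart")
    # balanced one-way oracle
    k, m = 8, 12
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(k * m)],
            "g": np.repeat([f"g{j}" for j in range(k)], m),
        }
    )
    diffs = []
    for _ in range(6):
        u = rng.normal(0, 1.0, size=k)
        y = np.repeat(u, m) + rng.normal(0, 0.7, size=k * m)
        grand = y.mean()
        means = pd.Series(y).groupby(table["g"].to_numpy()).mean()
        msb = m * ((means - grand) ** 2).sum() / (k - 1)
        msw = ((y - table["g"].map(means).to_numpy()) ** 2).sum() / (k * m - k)
        sig_a = max((msb - msw) / m, 0.0)
        vf = partition_variance(y, table, VarParSpec(["g"], []))
        diffs.append(abs(vf.fractions["g"] - sig_a / (sig_a + msw)))
    anova_max_diff = float(np.max(diffs))

    # planted 60% two-level fraction (component-variance convention)
    n2 = 200
    sex = rng.integers(0, 2, size=n2)
    t2 = pd.DataFrame(
        {
            "sample_id": [f"x{i}" for i in range(n2)],
            "sex": np.where(sex == 1, "Female", "Male"),
            "frip": rng.uniform(0.15, 0.35, size=n2),
        }
    )
    errs, sums = [], []
    for _ in range(5):
        y = np.sqrt(0.3) * 2 * (sex - 0.5) + rng.normal(0, np.sqrt(0.4), size=n2)
        vf = partition_variance(y, t2, VarParSpec(["sex"], ["frip"]))
        errs.append(vf.fractions["sex"] - 0.6)
        sums.append(abs(sum(vf.fractions.values()) - 1.0))
    return {
        "varpart_anova_oracle_max_abs_diff": anova_max_diff,
        "varpart_planted_sex_fraction_error": float(np.median(errs)),
        "varpart_fraction_sum_max_deviation": float(np.max(sums)),
        "n": n2,
    }


# ---------------------------------------------------------------------------
# 7. co-expression


def coexpression_checks(seed: int = 0) -> dict:
    rng = stream(seed, "coexpr-fwl")
    # FWL identity
    n = 120
    C = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n).astype(float)])
    fwl_diffs = []
    for _ in range(20):
        a = rng.normal(size=n)
        e = 0.6 * a + C @ rng.normal(size=3) + rng.normal(0, 0.4, n)
        slope, _, _ = association_test(e, a, C)
        joint = np.linalg.lstsq(np.column_stack([C, a]), e, rcond=None)[0][-1]
        fwl_diffs.append(abs(slope - joint))
    fwl_max = float(np.max(fwl_diffs))

    # planted-link recovery on the desk cohort
    cohort = simulate_cohort(CohortConfig(), seed=child_seed(seed, "coexpr-cohort"))
    sf = size_factors_median_of_ratios(cohort.counts)
    dm = estimate_dispersions(cohort.counts, sf)
    tm = vst(cohort.counts, sf, dm)
    res = map_all_pairs(
        cohort.expression, tm, cohort.genes, cohort.regions, cohort.metadata, alpha=0.01
    )
    links = cohort.truth.links
    pairs = res.pairs.set_index(["gene_id", "region_id"])
    found = sign_ok = 0
    for row in links.itertuples():
        key = (row.gene_id, row.region_id)
        if key in pairs.index and bool(pairs.loc[key, "significant"]):
            found += 1
            if np.sign(pairs.loc[key, "slope"]) == np.sign(row.slope):
                sign_ok += 1
    sensitivity = float(found / len(links))
    sign_agreement = float(sign_ok / found) if found else float("nan")

    # all-null cohort: no links planted
    null_cfg = CohortConfig(n_links=0, n_dual=0)
    null_cohort = simulate_cohort(null_cfg, seed=child_seed(seed, "coexpr-null"))
    sfn = size_factors_median_of_ratios(null_cohort.counts)
    dmn = estimate_dispersions(null_cohort.counts, sfn)
    tmn = vst(null_cohort.counts, sfn, dmn)
    null_res = map_all_pairs(
        null_cohort.expression,
        tmn,
        null_cohort.genes,
        null_cohort.regions,
        null_cohort.metadata,
        alpha=0.01,
    )
    m = null_res.summary["n_pairs_tested"]
    raw_sig = int((null_res.pairs["p"] < 0.01).sum())
    return {
        "coexpr_fwl_max_abs_diff": fwl_max,
        "coexpr_sensitivity": sensitivity,
        "coexpr_sign_agreement": sign_agreement,
        "coexpr_n_links_planted": int(len(links)),
        "coexpr_null_raw_sig_count": raw_sig,
        "coexpr_null_raw_expected": float(0.01 * m),
        "coexpr_null_raw_bound": float(0.01 * m + 3 * np.sqrt(0.01 * m * 0.99)),
        "coexpr_null_bonferroni_sig_count": int(null_res.summary["n_significant_pairs"]),
        "coexpr_n_pairs_tested": int(m),
        "n": null_res.summary["n_samples"],
    }


# ---------------------------------------------------------------------------
# 8. QC statistics


def qc_checks(seed: int = 0) -> dict:
    # exact consensus retention on an enumerable toy set: an interval shared
    # by exactly 2 of 20 samples survives the 10% threshold, 1 of 20 does not
    def _rs(triples, prefix):
        return RegionSet(
            [GenomicRegion(c, s, e, f"{prefix}{i}") for i, (c, s, e) in enumerate(triples)]
        )

    peaks = [_rs([("chr1", 100, 300)], f"a{i}") for i in range(2)]
    peaks += [_rs([("chr2", 100, 300)], "b0")]
    peaks += [_rs([], f"e{i}") for i in range(17)]
    cons = build_consensus(peaks, min_fraction=0.10)
    consensus_exact = float(
        [(r.chrom, r.start, r.end) for r in cons] == [("chr1", 100, 300)]
    )

    # exact IQR filter on the worked five-value example
    slopes = pd.Series([-5.0, -0.4, -0.3, -0.2, -0.1], index=list("abcde"))
    iqr_exact = float(iqr_outlier_filter(slopes) == ["a"])

    # exact RniP arithmetic
    toy = pd.DataFrame(
        {
            "sample_id": ["s0"],
            "sex": ["Female"],
            "total_reads": [10_000],
            "chrx_reads": [1_000],
            "chrx_reads_in_peaks": [400],
        }
    )
    rnip_value = float(chrx_rnip(toy).per_sample["rnip_normalized"].iloc[0])

    # planted female/male chrX background ratio and label-imputation
    # accuracy on the desk cohort
    cohort = simulate_cohort(CohortConfig(), seed=child_seed(seed, "qc-cohort"))
    res = chrx_rnip(cohort.metadata)
    ratio = float(res.group_medians["Female"] / res.group_medians["Male"])
    planted_ratio = cohort.config.rnip_female_ratio

    counts, meta, sf, dm = _qc_passing_cohort(cohort)
    tm = vst(counts, sf, dm)
    meta = meta.copy()
    rng = stream(seed, "qc-hide")
    known_idx = meta.index[meta["pbmc_type"].notna()]
    hide = rng.choice(known_idx, size=int(round(0.10 * len(known_idx))), replace=False)
    truth_labels = meta.loc[hide, "pbmc_type"].copy()
    meta.loc[hide, "pbmc_type"] = np.nan
    completed = impute_pbmc_labels(tm, meta, k=15)
    hidden_ids = meta.loc[hide, "sample_id"]
    accuracy = float(
        (completed[hidden_ids].to_numpy() == truth_labels.to_numpy()).mean()
    )
    return {
        "qc_consensus_toy_exact": consensus_exact,
        "qc_iqr_worked_example_exact": iqr_exact,
        "qc_rnip_toy_value": rnip_value,
        "qc_rnip_female_male_ratio": ratio,
        "qc_rnip_ratio_rel_error": float(abs(ratio - planted_ratio) / planted_ratio),
        "qc_impute_accuracy": accuracy,
        "qc_n_hidden_labels": int(len(hide)),
        "n": cohort.counts.n_samples,
    }
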