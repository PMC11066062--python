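"""ALSFRS-R slope prediction from TSS-proximal chromatin accessibility.

The procedure mirrors the clinical-progression predictor workflow:

1. subset the variance-stabilized matrix to regions within 2 kb of a TSS
   and to ALS cases with a recorded ALSFRS-R slope;
2. drop samples that are poorly correlated with the rest of the cohort
   (complete-link clustering of the inter-sample correlation matrix, with a
   guarded two-cluster cut);
3. drop samples whose slope lies more than 1.5 interquartile ranges outside
   the quartiles;
4. drop samples from differentiation batches with fewer than 4
   representatives in the remaining set;
5. split 90/10 into train/test (stratified by batch, fixed across reruns);
6. select regions by LASSO with ten-fold cross-validated regularization,
   rerun many times under random fold reassignment (stability selection);
   regions appearing in over half of the runs form the majority-vote set;
7. per run, refit the selected regions by OLS and evaluate on the held-out
   test set, with test R^2 anchored at the training mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rand import child_seed
from .io import TransformedMatrix
from .lasso import StandardizedProblem, cv_select_lambda
from .qc import guarded_correlation_split
from .regions import GeneRecord, RegionSet, nearest_tss_distance

__all__ = [
    "FilterReport",
    "StabilityRun",
    "StabilityResult",
    "PredictorModel",
    "subset_tss_regions",
    "correlation_outlier_filter",
    "iqr_outlier_filter",
    "batch_filter",
    "train_test_split_stratified",
    "stability_selection",
    "refit_ols_and_evaluate",
    "run_progression",
]


@dataclass
class FilterReport:
    """Which samples each staged filter removed, in application order."""

    excluded_by_correlation: list[str]
    excluded_by_slope_iqr: list[str]
    excluded_by_batch: list[str]
    retained: list[str]

    def __post_init__(self) -> None:
        sets = [
            set(self.excluded_by_correlation),
            set(self.excluded_by_slope_iqr),
            set(self.excluded_by_batch),
            set(self.retained),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("filter report groups overlap")

    def accounts_for(self, sample_ids: list[str]) -> bool:
        all_ids = (
            set(self.excluded_by_correlation)
            | set(self.excluded_by_slope_iqr)
            | set(self.excluded_by_batch)
            | set(self.retained)
        )
        return all_ids == set(sample_ids)


@dataclass
class StabilityRun:
    run_index: int
    fold_seed: int
    lambda_chosen: float
    selected_region_ids: list[str]
    train_rmse: float = math.nan
    train_r2: float = math.nan
    test_rmse: float = math.nan
    test_r2: float = math.nan


@dataclass
class StabilityResult:
    runs: list[StabilityRun]
    selection_frequency: pd.Series  # per region, over all runs
    majority_set: list[str]
    majority_threshold: float
    majority_denominator: str

    def support_sizes(self) -> np.ndarray:
        return np.array([len(r.selected_region_ids) for r in self.runs])

    def aggregate(self) -> pd.Series:
        """Mean and standard error of per-run metrics over non-empty runs.

        Runs whose support exceeded the training size carry NaN metrics
        (no OLS refit is possible) and are skipped metric-wise.
        """
        nonempty = [r for r in self.runs if r.selected_region_ids]
        out = {"n_runs": len(self.runs), "n_nonempty_runs": len(nonempty)}
        sizes = np.array([len(r.selected_region_ids) for r in nonempty], dtype=float)
        metrics = {
            "support_size": sizes,
            "train_rmse": np.array([r.train_rmse for r in nonempty]),
            "train_r2": np.array([r.train_r2 for r in nonempty]),
            "test_rmse": np.array([r.test_rmse for r in nonempty]),
            "test_r2": np.array([r.test_r2 for r in nonempty]),
        }
        for name, vals in metrics.items():
            vals = vals[np.isfinite(vals)]
            if len(vals):
                out[f"{name}_mean"] = float(np.mean(vals))
                out[f"{name}_se"] = (
                    float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
                )
        return pd.Series(out)


@dataclass
class PredictorModel:
    region_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    training_sample_ids: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coefficients


def subset_tss_regions(
    matrix: TransformedMatrix,
    region_set: RegionSet,
    genes: list[GeneRecord],
    halfwidth: int = 2000,
) -> TransformedMatrix:
    """Keep rows whose region center lies within ``halfwidth`` bp of a TSS."""
    dist = nearest_tss_distance(region_set, genes)
    keep = {
        r.region_id for r, d in zip(region_set, dist) if d <= halfwidth
    }
    ids = [rid for rid in matrix.region_ids if rid in keep]
    if not ids:
        raise ValueError("no region lies within the TSS window")
    return matrix.subset_regions(ids)


def correlation_outlier_filter(matrix: TransformedMatrix) -> list[str]:
    """Samples flagged by the guarded correlation-cluster cut.

    The inter-sample Pearson correlation matrix is clustered (complete link
    on Euclidean distances between its columns, cut into two).  The smaller
    cluster is excluded only when it holds under 20% of samples AND its
    members correlate less with the cohort than the larger cluster's members
    do; otherwise nothing is excluded.
    """
    if matrix.n_samples < 10:
        raise ValueError("need at least 10 samples for the correlation filter")
    flagged = guarded_correlation_split(matrix.values)
    return [matrix.sample_ids[j] for j in flagged]


def iqr_outlier_filter(slopes: pd.Series, multiplier: float = 1.5) -> list[str]:
    """Samples whose slope lies beyond ``multiplier`` IQRs outside Q1/Q3.

    Quartiles use linear interpolation (the type-7 convention).  Single-pass
    by contract: re-running on the retained set may flag more.
    """
    s = slopes.dropna()
    if len(s) < 4:
        raise ValueError("need at least 4 non-missing slopes")
    q1, q3 = np.percentile(s.to_numpy(dtype=float), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return s[(s < lo) | (s > hi)].index.tolist()


def batch_filter(sample_table: pd.DataFrame, min_per_batch: int = 4) -> list[str]:
    """Samples from batches with fewer than ``min_per_batch`` representatives.

    Counts are taken over the table as passed in — i.e. after any prior
    filtering.
    """
    counts = sample_table["diff_batch"].value_counts()
    small = counts[counts < min_per_batch].index
    mask = sample_table["diff_batch"].isin(small)
    return sample_table.loc[mask, "sample_id"].tolist()


def train_test_split_stratified(
    sample_table: pd.DataFrame,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Seeded train/test split stratified by differentiation batch.

    The target test size is ``ceil(test_fraction * n)``; test picks are
    spread over batches proportionally so the batch filter is not undone by
    the split.
    """
    n = len(sample_table)
    n_test = int(math.ceil(test_fraction * n))
    rng = np.random.default_rng(seed)
    test: list[str] = []
    groups = sorted(sample_table.groupby("diff_batch"), key=lambda kv: kv[0])
    quotas = []
    for batch, grp in groups:
        ids = grp["sample_id"].tolist()
        exact = test_fraction * len(ids)
        take = int(exact)
        quotas.append((batch, ids, exact - take))
        test.extend(rng.permutation(ids)[:take].tolist())
    # distribute the remainder to the batches with the largest fractional parts
    quotas.sort(key=lambda t: -t[2])
    i = 0
    while len(test) < n_test and i < len(quotas):
        batch, ids, _ = quotas[i]
        remaining = [s for s in ids if s not in set(test)]
        if remaining:
            test.append(rng.permutation(remaining)[0])
        i += 1
    test_set = set(test[:n_test])
    train = [s for s in sample_table["sample_id"] if s not in test_set]
    return train, sorted(test_set)


def refit_ols_and_evaluate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    region_ids: list[str],
    training_sample_ids: list[str] | None = None,
) -> tuple[PredictorModel, dict[str, float]]:
    """OLS refit on the selected regions; train-mean-anchored evaluation.

    ``R^2_test = 1 - sum (y - yhat)^2 / sum (y - mean(y_train))^2``, so a
    constant predictor at the training mean scores exactly zero.  The
    squared correlation corr(yhat, y)^2 is reported as a secondary metric.
    Rank-deficient selections fall back to the least-norm solution with a
    warning.
    """
    if len(region_ids) == 0:
        raise ValueError("empty selection")
    if len(region_ids) >= len(y_train):
        raise ValueError("more selected regions than training samples")
    A = np.column_stack([np.ones(len(y_train)), X_train])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient selection; using least-norm coefficients")
    coef, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    model = PredictorModel(
        list(region_ids), float(coef[0]), coef[1:], list(training_sample_ids or [])
    )
    ybar = float(np.mean(y_train))

    def _metrics(X, y):
        pred = model.predict(X)
        rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
        denom = float(np.sum((y - ybar) ** 2))
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / denom if denom > 0 else math.nan
        corr = (
            float(np.corrcoef(pred, y)[0, 1]) ** 2
            if np.std(pred) > 0 and np.std(y) > 0
            else math.nan
        )
        return rmse, r2, corr

    train_rmse, train_r2, _ = _metrics(X_train, y_train)
    test_rmse, test_r2, test_corr2 = _metrics(X_test, y_test)
    metrics = {
        "train_rmse": train_rmse,
        "train_r2": train_r2,
        "test_rmse": test_rmse,
        "test_r2": test_r2,
        "test_corr2": test_corr2,
    }
    return model, metrics


def stability_selection(
    X_train: np.ndarray,
    y_train: np.ndarray,
    region_ids: list[str],
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    n_runs: int = 1000,
    n_folds: int = 10,
    master_seed: int = 0,
    majority_threshold: float = 0.5,
    majority_denominator: str = "all",
    lambda_rule: str = "min",
) -> StabilityResult:
    """Rerun CV-LASSO feature selection under random fold reassignment.

    Each run draws a fold seed from the master seed, picks lambda by
    ten-fold CV, records the selected support, and (when test data are
    given) refits the support by OLS and evaluates train/test metrics.  The
    majority-vote set holds regions selected in more than
    ``majority_threshold`` of runs; the denominator counts all runs
    (including empty-support ones) by default, or only non-empty runs with
    ``majority_denominator="nonempty"``.
    """
    if majority_denominator not in {"all", "nonempty"}:
        raise ValueError("majority_denominator must be 'all' or 'nonempty'")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    full_problem = StandardizedProblem.from_data(X_train, y_train)
    runs: list[StabilityRun] = []
    counts = pd.Series(0, index=pd.Index(region_ids, name="region_id"), dtype=int)
    for r in range(n_runs):
        fold_seed = child_seed(master_seed, "fold", r)
        lam, _, _ = cv_select_lambda(
            X_train,
            y_train,
            n_folds=n_folds,
            fold_seed=fold_seed,
            full_problem=full_problem,
            rule=lambda_rule,
        )
        beta_std = full_problem.solve(lam)
        support = np.flatnonzero(beta_std)
        selected = [region_ids[j] for j in support]
        run = StabilityRun(r, fold_seed, lam, selected)
        if selected and X_test is not None and len(selected) < len(y_train):
            _, metrics = refit_ols_and_evaluate(
                X_train[:, support], y_train, X_test[:, support], y_test, selected
            )
            run.train_rmse = metrics["train_rmse"]
            run.train_r2 = metrics["train_r2"]
            run.test_rmse = metrics["test_rmse"]
            run.test_r2 = metrics["test_r2"]
        counts[selected] += 1
        runs.append(run)
    denom = n_runs if majority_denominator == "all" else max(
        sum(1 for r in runs if r.selected_region_ids), 1
    )
    freq = counts / denom
    majority = freq[freq > majority_threshold].index.tolist()
    return StabilityResult(runs, freq, majority, majority_threshold, majority_denominator)


@dataclass
class ProgressionResult:
    filter_report: FilterReport
    train_ids: list[str]
    test_ids: list[str]
    stability: StabilityResult
    majority_model: PredictorModel | None
    majority_metrics: dict[str, float] | None


def run_progression(
    matrix: TransformedMatrix,
    sample_table: pd.DataFrame,
    region_set: RegionSet,
    genes: list[GeneRecord],
    tss_halfwidth: int = 2000,
    iqr_multiplier: float = 1.5,
    min_per_batch: int = 4,
    test_fraction: float = 0.1,
    n_runs: int = 1000,
    n_folds: int = 10,
    master_seed: int = 0,
    majority_threshold: float = 0.5,
    majority_denominator: str = "all",
    lambda_rule: str = "min",
) -> ProgressionResult:
    """The full staged predictor: filters -> split -> stability -> refit.

    Filter order (correlation, slope IQR, batch) is fixed; the filter report
    accounts for every slope-carrying ALS sample.  The test set is fixed
    across all stability reruns.
    """
    table = sample_table.set_index("sample_id", drop=False)
    eligible = table[
        (table["case_status"] == "ALS") & table["alsfrs_r_slope"].notna()
    ]
    tss = subset_tss_regions(matrix, region_set, genes, tss_halfwidth)
    sub = tss.subset_samples(eligible["sample_id"].tolist())

    excl_corr = correlation_outlier_filter(sub)
    keep1 = [s for s in sub.sample_ids if s not in set(excl_corr)]

    excl_iqr = iqr_outlier_filter(
        table.loc[keep1, "alsfrs_r_slope"], multiplier=iqr_multiplier
    )
    keep2 = [s for s in keep1 if s not in set(excl_iqr)]

    excl_batch = batch_filter(table.loc[keep2], min_per_batch=min_per_batch)
    retained = [s for s in keep2 if s not in set(excl_batch)]

    report = FilterReport(excl_corr, excl_iqr, excl_batch, retained)
    if not report.accounts_for(eligible["sample_id"].tolist()):
        raise AssertionError("filter report does not account for all samples")

    split_seed = child_seed(master_seed, "split")
    train_ids, test_ids = train_test_split_stratified(
        table.loc[retained], test_fraction=test_fraction, seed=split_seed
    )
    Xtr = sub.subset_samples(train_ids).values.T
    Xte = sub.subset_samples(test_ids).values.T
    ytr = table.loc[train_ids, "alsfrs_r_slope"].to_numpy(dtype=float)
    yte = table.loc[test_ids, "alsfrs_r_slope"].to_numpy(dtype=float)

    stability = stability_selection(
        Xtr,
        ytr,
        sub.region_ids,
        X_test=Xte,
        y_test=yte,
        n_runs=n_runs,
        n_folds=n_folds,
        master_seed=master_seed,
        majority_threshold=majority_threshold,
        majority_denominator=majority_denominator,
        lambda_rule=lambda_rule,
    )
    majority_model = majority_metrics = None
    if stability.majority_set:
        idx = [sub.region_ids.index(rid) for rid in stability.majority_set]
        majority_model, majority_metrics = refit_ols_and_evaluate(
            Xtr[:, idx], ytr, Xte[:, idx], yte, stability.majority_set, train_ids
        )
    return ProgressionResult(report, train_ids, test_ids, stability, majority_model, majority_metrics)
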