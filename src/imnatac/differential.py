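"""Differential accessibility by negative-binomial GLM with covariates.

Each region's raw counts are modeled as NB with a log link and an offset for
the sample size factor:

    K_ij ~ NB(mean = s_j * exp(x_j' beta_i), dispersion = alpha_i)

Coefficients are estimated by iteratively reweighted least squares; the
contrast coefficient is tested with a two-sided Wald test against the
standard normal, and p-values are adjusted across regions by
Benjamini-Hochberg.  A region is called differentially accessible (DAR) when
it passes both the adjusted-p and |log2FC| thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import CountsMatrix
from .normalization import DispersionModel, SizeFactors, estimate_dispersions, size_factors_median_of_ratios

__all__ = [
    "DesignMatrix",
    "DifferentialResult",
    "build_design",
    "fit_nb_glm",
    "wald_test",
    "bh_adjust",
    "run_differential",
]

LN2 = np.log(2.0)


@dataclass
class DesignMatrix:
    """A full-rank design: intercept, covariates, contrast column last.

    Categorical covariates are treatment-coded with the alphabetically first
    observed level as reference, so a positive contrast coefficient means
    higher accessibility at the non-reference level.
    """

    X: np.ndarray
    columns: list[str]
    sample_ids: list[str]
    contrast_column: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError("design shape inconsistent with labels")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design contains missing values")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if self.contrast_column not in self.columns:
            raise ValueError(f"contrast column {self.contrast_column!r} not in design")

    @property
    def contrast_index(self) -> int:
        return self.columns.index(self.contrast_column)


_CONTINUOUS = {"frip", "onset_to_collection_years", "alsfrs_r_slope"}


def _encode(table: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    col = table[name]
    if name in _CONTINUOUS or pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None], [name]
    levels = sorted(col.dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"covariate {name!r} has fewer than 2 observed levels")
    cols = [(col == lev).to_numpy(dtype=float) for lev in levels[1:]]
    names = [f"{name}[{lev}]" for lev in levels[1:]]
    return np.column_stack(cols), names


def build_design(
    sample_table: pd.DataFrame,
    contrast: str,
    covariates: list[str] | None = None,
) -> DesignMatrix:
    """Treatment-coded design for ``contrast`` adjusted for ``covariates``.

    Rows with missing values in any used column are dropped.  The contrast
    must be a categorical column with exactly two observed levels (after
    dropping missing rows); its dummy is the last design column.
    """
    covariates = list(covariates or [])
    used = covariates + [contrast]
    table = sample_table.dropna(subset=used).reset_index(drop=True)
    levels = sorted(table[contrast].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"contrast {contrast!r} has fewer than 2 observed levels")
    blocks = [np.ones((len(table), 1))]
    names = ["intercept"]
    for cov in covariates:
        b, n = _encode(table, cov)
        blocks.append(b)
        names.extend(n)
    cb, cn = _encode(table, contrast)
    if cb.shape[1] != 1:
        raise ValueError(
            f"contrast {contrast!r} must have exactly 2 levels, found {levels}"
        )
    blocks.append(cb)
    names.extend(cn)
    X = np.column_stack(blocks)
    return DesignMatrix(X, names, list(table["sample_id"]), cn[0])


def fit_nb_glm(
    counts_row: np.ndarray,
    design: np.ndarray,
    size_factors: np.ndarray,
    alpha: float,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one NB-GLM row by IRLS; returns natural-log coefficients and covariance.

    Weights are ``mu / (1 + alpha * mu)`` (the expected-information weights
    for NB with known dispersion and log link).  Separation (a group with all
    zeros) is handled by damping non-intercept terms with a tiny ridge when
    the plain update diverges.  Non-convergence returns NaNs rather than
    raising, so callers can flag the row.
    """
    y = np.asarray(counts_row, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    offset = np.log(np.asarray(size_factors, dtype=float))
    if alpha < 0:
        raise ValueError("dispersion must be non-negative")

    beta = np.linalg.lstsq(X, np.log((y + 0.5) / np.exp(offset)), rcond=None)[0]
    damp = np.zeros(p)
    use_ridge = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        A = XtW @ X
        if use_ridge:
            A = A + np.diag(damp)
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            if not use_ridge:
                use_ridge = True
                damp = np.full(p, ridge)
                damp[0] = 0.0
                continue
            return np.full(p, np.nan), np.full((p, p), np.nan)
        if not np.all(np.isfinite(beta_new)) or np.max(np.abs(beta_new)) > 50:
            if not use_ridge:
                use_ridge = True
                damp = np.full(p, ridge)
                damp[0] = 0.0
                beta = np.clip(beta, -25, 25)
                continue
            return np.full(p, np.nan), np.full((p, p), np.nan)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            eta = np.clip(X @ beta + offset, -30, 30)
            mu = np.exp(eta)
            W = mu / (1.0 + alpha * mu)
            info = (X.T * W) @ X
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(info)
            return beta, cov
    return np.full(p, np.nan), np.full((p, p), np.nan)


def wald_test(beta: float, se: float) -> tuple[float, float]:
    """Two-sided Wald test of a single coefficient against the standard normal."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    z = beta / se
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (NaNs pass through)."""
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if np.any(ok):
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class DifferentialResult:
    """Per-region differential-accessibility statistics for one contrast."""

    table: pd.DataFrame  # region_id, base_mean, log2fc, se, wald_z, p, adj_p, is_dar
    contrast_column: str
    adj_p_threshold: float
    min_abs_log2fc: float

    @property
    def dar_ids(self) -> list[str]:
        return self.table.loc[self.table["is_dar"], "region_id"].tolist()


def run_differential(
    counts: CountsMatrix,
    sample_table: pd.DataFrame,
    contrast: str,
    covariates: list[str] | None = None,
    adj_p_threshold: float = 0.01,
    min_abs_log2fc: float = 0.5,
    size_factors: SizeFactors | None = None,
    dispersion: DispersionModel | None = None,
) -> DifferentialResult:
    """Differential accessibility of every region for one contrast.

    The design includes an intercept, the requested covariates, and the
    contrast dummy; size factors and the dispersion trend are estimated on
    the full counts matrix when not supplied.  Per-region dispersions are the
    MLE values; regions whose fit does not converge get NaN statistics and
    are excluded from multiplicity adjustment.
    """
    design = build_design(sample_table, contrast, covariates)
    sub = counts.subset_samples(design.sample_ids)
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(sub)
    else:
        size_factors = SizeFactors(
            np.asarray(
                [size_factors.s[size_factors.sample_ids.index(s)] for s in design.sample_ids]
            ),
            list(design.sample_ids),
        )
    if dispersion is None:
        dispersion = estimate_dispersions(sub, size_factors)

    k = design.contrast_index
    n_regions = sub.n_regions
    log2fc = np.full(n_regions, np.nan)
    se = np.full(n_regions, np.nan)
    zs = np.full(n_regions, np.nan)
    ps = np.full(n_regions, np.nan)
    base_mean = (sub.values / size_factors.s).mean(axis=1)

    alpha_by_region = dict(zip(dispersion.region_ids, dispersion.alpha_hat))
    for i in range(n_regions):
        row = sub.values[i]
        if not np.any(row > 0):
            continue
        alpha = alpha_by_region.get(sub.region_ids[i], np.nan)
        if not np.isfinite(alpha):
            continue
        beta, cov = fit_nb_glm(row, design.X, size_factors.s, alpha)
        if not np.isfinite(beta[k]) or not cov[k, k] > 0:
            continue
        se_nat = np.sqrt(cov[k, k])
        z, p = wald_test(beta[k], se_nat)
        log2fc[i] = beta[k] / LN2
        se[i] = se_nat / LN2
        zs[i] = z
        ps[i] = p

    adj = bh_adjust(ps)
    is_dar = (adj < adj_p_threshold) & (np.abs(log2fc) > min_abs_log2fc)
    is_dar = np.where(np.isfinite(adj) & np.isfinite(log2fc), is_dar, False)
    table = pd.DataFrame(
        {
            "region_id": sub.region_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_z": zs,
            "p": ps,
            "adj_p": adj,
            "is_dar": is_dar.astype(bool),
        }
    )
    return DifferentialResult(table, design.contrast_column, adj_p_threshold, min_abs_log2fc)
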