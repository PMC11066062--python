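"""Cis peak-gene co-expression mapping under covariate adjustment.

For every gene, all regions whose center lies within a cis window (default
250 kb) of its TSS are tested for association between region accessibility
and gene expression.  Both variables are residualized on the covariate
design (intercept + FRiP, sequencer, case status, sex, PBMC type) by least
squares; by the Frisch-Waugh-Lovell identity the residualized simple-
regression slope equals the accessibility coefficient of the joint multiple
regression.  The t statistic uses ``df = n - p_cov - 2`` (covariates,
intercept, and the accessibility term), and p-values are Bonferroni-
corrected over the number of pairs actually tested.

Pair classifications mirror the questions asked of such maps: sign of the
slope (about a third of real peak-gene pairs are inverse associations),
promoter proximity (|center - TSS| < 2.5 kb), and dual-sign peaks linked to
some genes positively and others negatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import TransformedMatrix
from .regions import GeneRecord, RegionSet, center_tss_distance

__all__ = [
    "pair_candidates",
    "association_test",
    "map_all_pairs",
    "CoexpressionResult",
]


def pair_candidates(
    genes: list[GeneRecord],
    region_set: RegionSet,
    window: int = 250_000,
) -> pd.DataFrame:
    """All same-chromosome (gene, region) pairs with |center - TSS| <= window.

    The returned distance is signed and strand-oriented (positive =
    downstream of the TSS).
    """
    by_chrom: dict[str, list] = {}
    for r in region_set:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda r: r.center)
    rows = []
    for gene in genes:
        regs = by_chrom.get(gene.chrom, [])
        centers = np.array([r.center for r in regs])
        lo = np.searchsorted(centers, gene.tss - window, side="left")
        hi = np.searchsorted(centers, gene.tss + window, side="right")
        for r in regs[lo:hi]:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "region_id": r.region_id,
                    "distance": center_tss_distance(r, gene),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "region_id", "distance"])


def _residualizer(C: np.ndarray) -> np.ndarray:
    """Projection onto the orthogonal complement of the covariate span."""
    Q, _ = np.linalg.qr(C)
    return np.eye(C.shape[0]) - Q @ Q.T


def association_test(
    expression: np.ndarray,
    accessibility: np.ndarray,
    covariate_design: np.ndarray,
) -> tuple[float, float, float]:
    """Covariate-adjusted association of one expression/accessibility pair.

    Returns ``(slope, t, p)`` from regressing expression residuals on
    accessibility residuals after projecting both off the covariate design
    (which must include an intercept column).
    """
    n = len(expression)
    p_cov = covariate_design.shape[1] - 1  # intercept not counted
    if n <= p_cov + 2:
        raise ValueError("too few samples for the covariate design")
    M = _residualizer(covariate_design)
    e = M @ expression
    a = M @ accessibility
    saa = float(a @ a)
    if saa < 1e-16:
        raise ValueError("accessibility has zero residual variance")
    slope = float(e @ a) / saa
    df = n - p_cov - 2
    rss = float(e @ e) - slope**2 * saa
    se = np.sqrt(max(rss, 0.0) / df / saa)
    if se == 0:
        return slope, np.inf, 0.0
    t = slope / se
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return slope, float(t), float(p)


_DEFAULT_COVARIATES = ["frip", "sequencer", "case_status", "sex", "pbmc_type"]


def _covariate_design(table: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(table))]
    for name in covariates:
        col = table[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
    X = np.column_stack(cols)
    # drop exactly collinear columns (e.g. a single-level factor)
    q = np.linalg.matrix_rank(X)
    if q < X.shape[1]:
        _, R = np.linalg.qr(X)
        keep = np.abs(np.diag(R)) > 1e-10
        X = X[:, keep]
    return X


@dataclass
class CoexpressionResult:
    pairs: pd.DataFrame  # all tested pairs with statistics and classes
    dual_sign_peaks: pd.DataFrame  # region_id, positive genes, negative genes
    summary: dict

    @property
    def significant(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"]]


def map_all_pairs(
    expression: pd.DataFrame,
    accessibility: TransformedMatrix,
    genes: list[GeneRecord],
    region_set: RegionSet,
    sample_table: pd.DataFrame,
    window: int = 250_000,
    alpha: float = 0.01,
    proximal_bp: int = 2_500,
    covariates: list[str] | None = None,
    min_sd: float = 1e-8,
) -> CoexpressionResult:
    """Test every cis candidate pair and classify the significant ones.

    Sample matching: only samples present in both matrices (and the
    metadata) are used.  Bonferroni ``m`` is the number of pairs actually
    tested (post pairing and variance filtering).  Missing covariate levels
    (e.g. unlabeled PBMC type) are treated as their own level so samples are
    not dropped.
    """
    covariates = covariates if covariates is not None else list(_DEFAULT_COVARIATES)
    shared = [s for s in accessibility.sample_ids if s in set(expression.columns)]
    meta = sample_table.set_index("sample_id").reindex(shared)
    n = len(shared)
    C = _covariate_design(meta.fillna("missing"), covariates)
    if n <= C.shape[1] + 2:
        raise ValueError("too few overlapping samples for the covariate design")

    cands = pair_candidates(genes, region_set, window)
    if cands.empty:
        raise ValueError("no candidate pairs in the cis window")

    M = _residualizer(C)
    acc = accessibility.subset_samples(shared)
    E = expression[shared]
    # residualize every row of both matrices once
    A_res = acc.values @ M.T
    E_res = E.to_numpy(dtype=float) @ M.T

    region_idx = {r: i for i, r in enumerate(acc.region_ids)}
    gene_idx = {g: i for i, g in enumerate(E.index)}
    cands = cands[
        cands["region_id"].isin(region_idx) & cands["gene_id"].isin(gene_idx)
    ].reset_index(drop=True)

    ai = cands["region_id"].map(region_idx).to_numpy()
    gi = cands["gene_id"].map(gene_idx).to_numpy()
    a = A_res[ai]
    e = E_res[gi]
    saa = np.einsum("ij,ij->i", a, a)
    see = np.einsum("ij,ij->i", e, e)
    ok = (np.sqrt(saa / n) > min_sd) & (np.sqrt(see / n) > min_sd)
    cands = cands[ok].reset_index(drop=True)
    a, e, saa = a[ok], e[ok], saa[ok]

    sea = np.einsum("ij,ij->i", e, a)
    slope = sea / saa
    p_cov = C.shape[1] - 1
    df = n - p_cov - 2
    rss = np.maximum(np.einsum("ij,ij->i", e, e) - slope**2 * saa, 0.0)
    se = np.sqrt(rss / df / saa)
    with np.errstate(divide="ignore"):
        t = np.where(se > 0, slope / se, np.inf)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    m = len(cands)
    adj_p = np.minimum(p * m, 1.0)

    pairs = cands.assign(
        slope=slope,
        t_stat=t,
        p=p,
        adj_p=adj_p,
        significant=adj_p < alpha,
        sign=np.where(slope >= 0, "positive", "negative"),
        promoter_proximal=cands["distance"].abs() < proximal_bp,
    )

    sig = pairs[pairs["significant"]]
    per_region = sig.groupby("region_id")
    dual_rows = []
    for rid, grp in per_region:
        pos = grp.loc[grp["slope"] > 0, "gene_id"].tolist()
        neg = grp.loc[grp["slope"] < 0, "gene_id"].tolist()
        if pos and neg:
            dual_rows.append(
                {"region_id": rid, "positive_genes": pos, "negative_genes": neg}
            )
    dual = pd.DataFrame(dual_rows, columns=["region_id", "positive_genes", "negative_genes"])

    summary = {
        "n_pairs_tested": int(m),
        "n_samples": int(n),
        "n_significant_pairs": int(sig.shape[0]),
        "n_significant_genes": int(sig["gene_id"].nunique()),
        "n_significant_regions": int(sig["region_id"].nunique()),
        "negative_fraction_significant": float(
            (sig["slope"] < 0).mean() if len(sig) else np.nan
        ),
        "n_dual_sign_peaks": int(len(dual)),
        "median_peaks_per_gene": float(
            sig.groupby("gene_id").size().median() if len(sig) else np.nan
        ),
    }
    return CoexpressionResult(pairs, dual, summary)
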