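"""Cohort-level QC: variable regions, PCA, correlation clustering, PBMC-label
imputation, and the chrX reads-not-in-peaks statistic.

The reads-not-in-peaks (RniP) statistic quantifies background reads from the
inactivated X chromosome: in females one X is silenced, so its fragments
fall mostly outside called peaks, roughly doubling the normalized chrX
background relative to males.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

from .io import TransformedMatrix

__all__ = [
    "PcaResult",
    "RnipResult",
    "top_variable_regions",
    "pca",
    "impute_pbmc_labels",
    "chrx_rnip",
    "inter_sample_correlation_cluster",
    "guarded_correlation_split",
]


def top_variable_regions(matrix: TransformedMatrix, n: int) -> list[str]:
    """The ``n`` regions with the largest across-sample variance.

    Ties break by region-id order, so the selection is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > matrix.n_regions:
        raise ValueError("n exceeds the number of regions")
    var = matrix.values.var(axis=1)
    order = sorted(range(matrix.n_regions), key=lambda i: (-var[i], matrix.region_ids[i]))
    return [matrix.region_ids[i] for i in order[:n]]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # regions x components
    variance_fractions: np.ndarray


def pca(matrix: TransformedMatrix, region_ids: list[str] | None = None, n_components: int = 10) -> PcaResult:
    """Column-centered SVD with samples as observations."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sub = matrix.subset_regions(region_ids) if region_ids is not None else matrix
    A = sub.values.T.astype(float)  # samples x regions
    A = A - A.mean(axis=0, keepdims=True)
    if np.allclose(A, 0):
        raise ValueError("matrix is constant across samples")
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    k = min(n_components, len(S))
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * S[:k], index=sub.sample_ids, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=sub.region_ids, columns=comps)
    frac = (S**2) / float((S**2).sum())
    return PcaResult(scores, loadings, frac[:k])


def impute_pbmc_labels(
    matrix: TransformedMatrix,
    sample_table: pd.DataFrame,
    k: int = 15,
    n_top_regions: int = 100,
) -> pd.Series:
    """Fill missing PBMC-type labels by neighborhood vote in PC space.

    Samples are embedded in the top-2 principal components of the most
    variable regions; each unlabeled sample takes the majority label of its
    ``k`` nearest labeled neighbors (Euclidean distance), falling back to
    the single nearest neighbor on ties.
    """
    labels = sample_table.set_index("sample_id")["pbmc_type"].reindex(matrix.sample_ids)
    labeled = labels.dropna()
    if len(labeled) < k:
        raise ValueError(f"need at least k={k} labeled samples, have {len(labeled)}")
    if labels.notna().all():
        return labels
    top = top_variable_regions(matrix, min(n_top_regions, matrix.n_regions))
    emb = pca(matrix, top, n_components=2).scores
    lab_idx = [matrix.sample_ids.index(s) for s in labeled.index]
    out = labels.copy()
    for sid in labels.index[labels.isna()]:
        x = emb.loc[sid].to_numpy()
        d = np.linalg.norm(emb.iloc[lab_idx].to_numpy() - x, axis=1)
        nearest = np.argsort(d, kind="stable")[:k]
        votes = labeled.iloc[nearest].value_counts()
        if len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
            out[sid] = labeled.iloc[nearest[0]]
        else:
            out[sid] = votes.index[0]
    return out


@dataclass
class RnipResult:
    per_sample: pd.DataFrame  # sample_id, sex, rnip_normalized
    group_medians: pd.Series  # by sex
    mannwhitney_u: float
    mannwhitney_p: float


def chrx_rnip(sample_table: pd.DataFrame) -> RnipResult:
    """Normalized chrX reads-not-in-peaks per sample, summarized by sex.

    ``rnip = (chrx_reads - chrx_reads_in_peaks) / total_reads``; the
    female/male comparison is reported descriptively with a two-sided
    Mann-Whitney test.
    """
    t = sample_table
    if (t["chrx_reads_in_peaks"] > t["chrx_reads"]).any():
        raise ValueError("chrx_reads_in_peaks exceeds chrx_reads")
    rnip = (t["chrx_reads"] - t["chrx_reads_in_peaks"]) / t["total_reads"]
    per_sample = pd.DataFrame(
        {"sample_id": t["sample_id"], "sex": t["sex"], "rnip_normalized": rnip}
    )
    medians = per_sample.groupby("sex")["rnip_normalized"].median()
    f = per_sample.loc[per_sample["sex"] == "Female", "rnip_normalized"]
    m = per_sample.loc[per_sample["sex"] == "Male", "rnip_normalized"]
    if len(f) and len(m):
        u, p = scipy.stats.mannwhitneyu(f, m, alternative="two-sided")
    else:
        u, p = float("nan"), float("nan")
    return RnipResult(per_sample, medians, float(u), float(p))


def guarded_correlation_split(
    values: np.ndarray,
    max_outlier_fraction: float = 0.20,
    min_correlation_gap: float = 0.1,
) -> list[int]:
    """Indices of samples excluded by the guarded two-cluster correlation cut.

    Columns of the sample-correlation matrix are clustered by complete-link
    agglomeration on their Euclidean distances and cut into two clusters.
    The smaller cluster is flagged only when (a) it holds fewer than
    ``max_outlier_fraction`` of samples and (b) its members' mean
    off-diagonal correlation with the cohort is materially lower than the
    larger cluster's (by at least ``min_correlation_gap``); otherwise
    nothing is flagged.  Without the margin, guard (b) would trip on the
    infinitesimally lower correlation of whichever side of a homogeneous
    cohort the two-cluster cut happens to separate.
    """
    n = values.shape[1]
    C = np.corrcoef(values.T)
    D = scipy.spatial.distance.pdist(C.T, metric="euclidean")
    Z = scipy.cluster.hierarchy.linkage(D, method="complete")
    labels = scipy.cluster.hierarchy.fcluster(Z, t=2, criterion="maxclust")
    sizes = np.bincount(labels)[1:]
    if len(sizes) < 2:
        return []
    small_label = int(np.argmin(sizes)) + 1
    small = np.flatnonzero(labels == small_label)
    large = np.flatnonzero(labels != small_label)
    if len(small) == len(large):
        return []
    if len(small) >= max_outlier_fraction * n:
        return []
    off = C.copy()
    np.fill_diagonal(off, np.nan)
    mean_small = np.nanmean(off[small])
    mean_large = np.nanmean(off[large])
    if not mean_small < mean_large - min_correlation_gap:
        return []
    return small.tolist()


@dataclass
class CorrelationClusterResult:
    linkage: np.ndarray
    correlation: np.ndarray
    flagged_sample_ids: list[str]


def inter_sample_correlation_cluster(matrix: TransformedMatrix) -> CorrelationClusterResult:
    """Complete-link dendrogram over the inter-sample correlation matrix,
    with outliers flagged by the shared guarded two-cluster cut."""
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    C = np.corrcoef(matrix.values.T)
    D = scipy.spatial.distance.pdist(C, metric="euclidean")
    Z = scipy.cluster.hierarchy.linkage(D, method="complete")
    flagged = guarded_correlation_split(matrix.values)
    return CorrelationClusterResult(Z, C, [matrix.sample_ids[j] for j in flagged])
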