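"""In-memory containers and plain-text I/O for counts and sample metadata.

Counts travel as a region x sample integer matrix (TSV with region_id rows
and sample_id columns, or MatrixMarket MTX plus sidecar id lists).  Sample
metadata is a TSV with one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountsMatrix",
    "TransformedMatrix",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_sample_table",
    "write_sample_table",
    "validate_sample_table",
    "SAMPLE_TABLE_COLUMNS",
]


@dataclass
class CountsMatrix:
    """Raw fragment counts, regions x samples, with aligned identifiers."""

    values: np.ndarray
    region_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.region_ids = [str(r) for r in self.region_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.values.shape != (len(self.region_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.values.shape} inconsistent with "
                f"{len(self.region_ids)} regions x {len(self.sample_ids)} samples"
            )
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts must be integral")
            self.values = np.round(self.values).astype(np.int64)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountsMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def subset_regions(self, region_ids: Sequence[str]) -> "CountsMatrix":
        idx = {r: i for i, r in enumerate(self.region_ids)}
        rows = [idx[r] for r in region_ids]
        return CountsMatrix(self.values[rows], list(region_ids), self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountsMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountsMatrix(self.values[:, cols], self.region_ids, list(sample_ids))


@dataclass
class TransformedMatrix:
    """Variance-stabilized (or otherwise transformed) values, regions x samples."""

    values: np.ndarray
    region_ids: list[str]
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = [str(r) for r in self.region_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.region_ids), len(self.sample_ids)):
            raise ValueError("transformed matrix shape inconsistent with id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("transformed values must be finite")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "TransformedMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), meta or {})

    def subset_regions(self, region_ids: Sequence[str]) -> "TransformedMatrix":
        idx = {r: i for i, r in enumerate(self.region_ids)}
        rows = [idx[r] for r in region_ids]
        return TransformedMatrix(self.values[rows], list(region_ids), self.sample_ids, dict(self.meta))

    def subset_samples(self, sample_ids: Sequence[str]) -> "TransformedMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return TransformedMatrix(self.values[:, cols], self.region_ids, list(sample_ids), dict(self.meta))


def read_counts_tsv(path: str | Path) -> CountsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountsMatrix.from_frame(df)


def write_counts_tsv(counts: CountsMatrix, path: str | Path) -> None:
    df = counts.to_frame()
    df.index.name = "region_id"
    df.to_csv(path, sep="\t")


def read_counts_mtx(
    mtx_path: str | Path,
    regions_path: str | Path,
    samples_path: str | Path,
) -> CountsMatrix:
    """Read counts from MatrixMarket plus one-id-per-line sidecar files."""
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    region_ids = Path(regions_path).read_text().split()
    sample_ids = Path(samples_path).read_text().split()
    return CountsMatrix(np.asarray(mat), region_ids, sample_ids)


def write_counts_mtx(
    counts: CountsMatrix,
    mtx_path: str | Path,
    regions_path: str | Path,
    samples_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(counts.values))
    Path(regions_path).write_text("\n".join(counts.region_ids) + "\n")
    Path(samples_path).write_text("\n".join(counts.sample_ids) + "\n")


#: Required columns of the per-sample metadata table.
SAMPLE_TABLE_COLUMNS = [
    "sample_id",
    "sex",
    "pbmc_type",
    "sequencer",
    "frip",
    "diff_batch",
    "ancestry",
    "case_status",
    "c9_status",
    "alsfrs_r_slope",
    "onset_to_collection_years",
    "total_reads",
    "chrx_reads",
    "chrx_reads_in_peaks",
]

_SEX_LEVELS = {"Female", "Male"}
_PBMC_LEVELS = {"T-cell", "non-T-cell"}
_CASE_LEVELS = {"ALS", "HC"}
_C9_LEVELS = {"POS", "NEG"}


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-sample covariate table and return it unchanged.

    ``pbmc_type``, ``c9_status``, ``alsfrs_r_slope`` and
    ``onset_to_collection_years`` may be missing (NaN); read counts must obey
    ``chrx_reads_in_peaks <= chrx_reads <= total_reads``.
    """
    missing = set(SAMPLE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids")
    bad_sex = set(table["sex"].dropna()) - _SEX_LEVELS
    if bad_sex:
        raise ValueError(f"unknown sex levels: {sorted(bad_sex)}")
    bad_pbmc = set(table["pbmc_type"].dropna()) - _PBMC_LEVELS
    if bad_pbmc:
        raise ValueError(f"unknown pbmc_type levels: {sorted(bad_pbmc)}")
    bad_case = set(table["case_status"].dropna()) - _CASE_LEVELS
    if bad_case:
        raise ValueError(f"unknown case_status levels: {sorted(bad_case)}")
    bad_c9 = set(table["c9_status"].dropna()) - _C9_LEVELS
    if bad_c9:
        raise ValueError(f"unknown c9_status levels: {sorted(bad_c9)}")
    frip = table["frip"].to_numpy(dtype=float)
    if np.any((frip < 0) | (frip > 1)):
        raise ValueError("frip must lie in [0, 1]")
    total = table["total_reads"].to_numpy(dtype=float)
    chrx = table["chrx_reads"].to_numpy(dtype=float)
    rip = table["chrx_reads_in_peaks"].to_numpy(dtype=float)
    if np.any(rip > chrx) or np.any(chrx > total):
        raise ValueError("expected chrx_reads_in_peaks <= chrx_reads <= total_reads")
    return table


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "diff_batch": str, "sequencer": str})
    return validate_sample_table(df)


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_sample_table(table).to_csv(path, sep="\t", index=False)
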