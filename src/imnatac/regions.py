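"""Genomic regions: BED I/O, consensus-peak construction, annotation.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A region's center is ``floor((start + end) / 2)`` and is
the anchor for promoter annotation and peak-to-TSS distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "GeneRecord",
    "RegionSet",
    "read_regions_bed",
    "write_regions_bed",
    "read_gene_table",
    "write_gene_table",
    "build_consensus",
    "annotate_regions",
    "center_tss_distance",
]

PROMOTER_TSS = "promoter_tss"
GENIC_OTHER = "genic_other"
INTRONIC_INTERGENIC = "intronic_intergenic"
_ANNOTATIONS = {PROMOTER_TSS, GENIC_OTHER, INTRONIC_INTERGENIC}


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval with a stable identifier."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region {self.region_id!r}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )
        if self.start < 0:
            raise ValueError(f"region {self.region_id!r}: negative start")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored by its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative TSS")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")


class RegionSet:
    """An ordered, duplicate-free collection of regions.

    Regions are kept sorted by ``(chrom, start)``.  An optional per-region
    annotation label (``promoter_tss`` / ``genic_other`` /
    ``intronic_intergenic``) may be attached by :func:`annotate_regions`.
    """

    def __init__(
        self,
        regions: Iterable[GenomicRegion],
        annotation: Sequence[str] | None = None,
    ) -> None:
        regs = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
        ids = [r.region_id for r in regs]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            dup = dup[dup > 1].index.tolist()
            raise ValueError(f"duplicate region_ids: {dup[:5]}")
        self.regions: list[GenomicRegion] = regs
        if annotation is not None:
            annotation = list(annotation)
            if len(annotation) != len(regs):
                raise ValueError("annotation length does not match region count")
            bad = set(annotation) - _ANNOTATIONS
            if bad:
                raise ValueError(f"unknown annotation labels: {sorted(bad)}")
        self.annotation: list[str] | None = annotation

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def by_id(self, region_id: str) -> GenomicRegion:
        try:
            return next(r for r in self.regions if r.region_id == region_id)
        except StopIteration:
            raise KeyError(region_id) from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "region_id": [r.region_id for r in self.regions],
            }
        )
        if self.annotation is not None:
            df["annotation"] = self.annotation
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        regions = [
            GenomicRegion(str(c), int(s), int(e), str(i))
            for c, s, e, i in zip(df["chrom"], df["start"], df["end"], df["region_id"])
        ]
        annotation = df["annotation"].tolist() if "annotation" in df.columns else None
        return cls(regions, annotation=annotation)


def read_regions_bed(path: str | Path) -> RegionSet:
    """Read a 3+ column BED file (0-based half-open) into a :class:`RegionSet`.

    Column 4, when present, is taken as the region id; otherwise ids are
    synthesized as ``chrom:start-end``.  Malformed lines raise a parse error
    naming the offending line number.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            region_id = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            try:
                regions.append(GenomicRegion(chrom, start, end, region_id))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(regions)


def write_regions_bed(region_set: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in region_set:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV gene table with header ``gene_id  chrom  tss  strand``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    return [
        GeneRecord(row.gene_id, row.chrom, int(row.tss), row.strand)
        for row in df.itertuples()
    ]


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def build_consensus(
    per_sample_peaks: Sequence[RegionSet],
    min_fraction: float = 0.10,
) -> RegionSet:
    """Construct a consensus peak set from per-sample peak sets.

    Candidate intervals are the maximal unions of overlapping per-sample
    peaks; a candidate is retained iff at least ``ceil(min_fraction *
    n_samples)`` samples have >= 1 bp overlap with it ("open in at least
    ``min_fraction`` of samples").  Retained intervals keep their union span,
    so consensus regions have variable width.
    """
    if len(per_sample_peaks) == 0:
        raise ValueError("need at least one per-sample peak set")
    if not (0 < min_fraction <= 1):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    n_samples = len(per_sample_peaks)
    threshold = math.ceil(min_fraction * n_samples)

    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for sample_idx, peaks in enumerate(per_sample_peaks):
        for r in peaks:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end, sample_idx))

    retained: list[GenomicRegion] = []
    for chrom in sorted(by_chrom):
        ivals = sorted(by_chrom[chrom])
        cur_start, cur_end, cur_samples = ivals[0][0], ivals[0][1], {ivals[0][2]}
        groups: list[tuple[int, int, set[int]]] = []
        for start, end, sidx in ivals[1:]:
            if start < cur_end:  # half-open: >=1 bp shared
                cur_end = max(cur_end, end)
                cur_samples.add(sidx)
            else:
                groups.append((cur_start, cur_end, cur_samples))
                cur_start, cur_end, cur_samples = start, end, {sidx}
        groups.append((cur_start, cur_end, cur_samples))
        for start, end, samples in groups:
            if len(samples) >= threshold:
                retained.append(
                    GenomicRegion(chrom, start, end, f"{chrom}:{start}-{end}")
                )
    return RegionSet(retained)


def _tss_by_chrom(genes: Sequence[GeneRecord]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.tss)
    return {c: np.asarray(sorted(t)) for c, t in by_chrom.items()}


def nearest_tss_distance(
    region_set: RegionSet, genes: Sequence[GeneRecord]
) -> np.ndarray:
    """Unsigned bp distance from each region center to its nearest same-chromosome TSS.

    Regions on chromosomes with no annotated gene get ``inf``.
    """
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    tss = _tss_by_chrom(genes)
    out = np.full(len(region_set), np.inf)
    for i, r in enumerate(region_set):
        arr = tss.get(r.chrom)
        if arr is None:
            continue
        j = np.searchsorted(arr, r.center)
        cands = arr[max(j - 1, 0) : j + 1]
        out[i] = np.abs(cands - r.center).min()
    return out


def annotate_regions(
    region_set: RegionSet,
    genes: Sequence[GeneRecord],
    promoter_halfwidth: int = 2000,
) -> RegionSet:
    """Label regions as ``promoter_tss`` when their center lies within
    ``promoter_halfwidth`` bp of any TSS, else ``intronic_intergenic``.

    This is a deliberately simple distance rule standing in for a full
    annotator; ``genic_other`` is reserved for gene-body overlap when gene
    spans are available.
    """
    dist = nearest_tss_distance(region_set, genes)
    labels = [
        PROMOTER_TSS if d <= promoter_halfwidth else INTRONIC_INTERGENIC for d in dist
    ]
    return RegionSet(list(region_set), annotation=labels)


def center_tss_distance(region: GenomicRegion, gene: GeneRecord) -> int:
    """Signed bp distance from a region center to a gene TSS.

    Positive values are downstream of the TSS in the gene's direction of
    transcription.
    """
    if region.chrom != gene.chrom:
        raise ValueError(
            f"region {region.region_id!r} on {region.chrom} but gene "
            f"{gene.gene_id!r} on {gene.chrom}"
        )
    d = region.center - gene.tss
    return d if gene.strand == "+" else -d
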