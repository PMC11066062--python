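"""Synthetic ATAC-seq cohort generator with planted, recorded effects.

The generator emulates a bulk ATAC-seq cohort of iPSC-derived motor-neuron
lines: negative-binomial fragment counts over a catalog of genomic regions
with a dispersion-mean trend, per-sample depth factors, and planted
covariate effects mirroring the structure such cohorts exhibit —

* sex structure: chrY regions essentially unreadable in females, an
  XIST-like X-escape region far more accessible in females (|log2FC| = 4),
  and a handful of autosomal sex regions;
* iPSC source-cell ("epigenetic memory") structure: TCR-locus-like regions
  nearly deleted in T-cell-derived samples plus milder memory regions;
* technical structure: sequencer- and FRiP-dependent regions and
  differentiation-batch random shifts;
* ancestry-variant regions;
* a C9orf72-like promoter decrease (log2FC = -0.6) in repeat-expansion
  carriers;
* a multifactorial progression-rate signal: the ALSFRS-R slope of each case
  is linear in the measured accessibility of a small set of promoter
  "driver" regions plus noise (two-pass generation: counts first, then
  slopes), so predictor recovery is testable against ground truth;
* planted sample-level pathologies for the predictor's filter chain:
  decorrelated samples, extreme-slope samples, and under-filled batches.

Every planted quantity is recorded in a :class:`GroundTruth` ledger so that
downstream modules can be tested as recovery problems.  All randomness is
drawn from named streams of a single seed; the same (config, seed) pair
reproduces the cohort exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rand import stream
from .io import CountsMatrix, validate_sample_table, write_counts_tsv, write_sample_table
from .regions import GeneRecord, GenomicRegion, RegionSet, write_gene_table, write_regions_bed

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "build_region_catalog",
    "simulate_metadata",
    "simulate_counts",
    "simulate_expression",
    "simulate_peaks",
    "simulate_cohort",
    "write_cohort",
]

_GENE_SPACING = 40_000
_CHROMS_AUTOSOMAL = ["chr1", "chr2", "chr3", "chr4", "chr5"]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    The desk-scale defaults describe a cohort of 220 motor-neuron lines
    (190 ALS cases / 30 healthy controls) over ~5,000 regions and 1,000
    genes; 180 cases carry a recorded ALSFRS-R slope, of which 12 are
    planted as decorrelated samples, 6 as slope outliers, and 6 sit in
    under-filled differentiation batches, so the progression filter chain
    retains 156 samples (a 140/16 train/test split at a 10% test fraction).
    """

    # cohort composition
    n_cases: int = 190
    n_controls: int = 30
    n_missing_slope_cases: int = 10
    female_fraction: float = 0.43
    tcell_fraction: float = 0.5
    pbmc_missing_fraction: float = 0.05
    afr_fraction: float = 0.10
    novaseq_fraction: float = 0.5
    c9_pos: int = 27
    c9_neg: int = 112
    frip_mean: float = 0.24
    frip_sd: float = 0.05
    # planted sample pathologies for the predictor filter chain
    n_corr_outliers: int = 12
    n_iqr_outliers: int = 6
    n_small_batch_samples: int = 6
    small_batch_size: int = 3
    main_batch_size: int = 12
    # region catalog (two promoter regions + one distal region per gene,
    # plus special-effect blocks and filler)
    n_genes: int = 1000
    n_filler: int = 860
    n_chrx: int = 248
    n_xist: int = 2
    n_chry: int = 40
    n_sex_autosomal: int = 10
    n_tcr: int = 8
    n_pbmc_memory: int = 180
    n_ancestry: int = 47
    n_c9: int = 5
    n_case_effect: int = 100
    n_sequencer_effect: int = 150
    n_frip_effect: int = 150
    n_batch_effect: int = 200
    n_decoy: int = 100
    # planted effect sizes (log2 scale)
    lfc_chry_female: float = -8.0
    lfc_xist_female: float = 4.0
    lfc_sex_autosomal: float = 1.2
    lfc_tcr_tcell: float = -3.0
    lfc_pbmc_memory: float = 0.8
    lfc_ancestry: float = 0.8
    lfc_c9: float = -0.6
    lfc_case: float = 0.3
    lfc_sequencer: float = 0.4
    frip_coef: float = 4.0
    batch_effect_sd: float = 0.3
    # negative-binomial machinery
    alpha0: float = 0.05
    a1: float = 3.0
    dispersion_scatter_sd: float = 0.3
    base_log2_mean_range: tuple[float, float] = (3.0, 8.0)
    promoter_log2_boost: float = 1.5
    depth_log2_range: tuple[float, float] = (-1.0, 1.0)
    # progression signal
    n_drivers: int = 25
    driver_signal_sd: float = 0.5
    slope_noise_sd: float = 0.1
    slope_mean: float = -0.8
    # peak-gene co-expression links
    n_links: int = 60
    n_dual: int = 10
    link_slope_range: tuple[float, float] = (0.8, 1.6)
    link_negative_fraction: float = 1 / 3
    expr_noise_sd: float = 0.5
    expr_sample_fraction: float = 0.8
    coexpr_window: int = 250_000
    # chrX background-read statistics
    rnip_male_rate: float = 0.02
    rnip_female_ratio: float = 2.0
    rnip_noise_sd: float = 0.1
    peak_x_rate: float = 0.01
    mean_total_reads: float = 4.0e7

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_regions(self) -> int:
        return 3 * self.n_genes + self.n_special + self.n_filler

    @property
    def n_special(self) -> int:
        return (
            self.n_chrx
            + self.n_xist
            + self.n_chry
            + self.n_sex_autosomal
            + self.n_tcr
            + self.n_pbmc_memory
            + self.n_ancestry
            + self.n_c9
            + self.n_case_effect
            + self.n_sequencer_effect
            + self.n_frip_effect
            + self.n_batch_effect
        )

    def validate(self) -> "CohortConfig":
        for name in (
            "female_fraction",
            "tcell_fraction",
            "pbmc_missing_fraction",
            "afr_fraction",
            "novaseq_fraction",
            "expr_sample_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.alpha0 < 0 or self.a1 < 0:
            raise ValueError("dispersion trend parameters must be non-negative")
        if self.c9_pos + self.c9_neg > self.n_cases - self.n_corr_outliers:
            raise ValueError("C9 group sizes exceed the number of QC-passing cases")
        n_with_slope = self.n_cases - self.n_missing_slope_cases
        planted = self.n_corr_outliers + self.n_iqr_outliers + self.n_small_batch_samples
        if planted > n_with_slope:
            raise ValueError("planted outliers exceed cases with a recorded slope")
        if self.n_small_batch_samples % self.small_batch_size != 0:
            raise ValueError("n_small_batch_samples must be a multiple of small_batch_size")
        if self.n_drivers > 2 * self.n_genes:
            raise ValueError("more drivers than promoter regions")
        if self.n_links + 2 * self.n_dual > self.n_genes:
            raise ValueError("more linked genes than genes")
        return self

    @classmethod
    def tiny(cls) -> "CohortConfig":
        """A fast configuration for unit tests (40 samples, ~150 regions)."""
        return cls(
            n_cases=32,
            n_controls=8,
            n_missing_slope_cases=2,
            c9_pos=6,
            c9_neg=14,
            n_corr_outliers=3,
            n_iqr_outliers=2,
            n_small_batch_samples=3,
            small_batch_size=3,
            main_batch_size=6,
            n_genes=30,
            n_filler=10,
            n_chrx=6,
            n_xist=1,
            n_chry=4,
            n_sex_autosomal=2,
            n_tcr=2,
            n_pbmc_memory=6,
            n_ancestry=4,
            n_c9=2,
            n_case_effect=4,
            n_sequencer_effect=4,
            n_frip_effect=4,
            n_batch_effect=6,
            n_decoy=8,
            n_drivers=5,
            n_links=8,
            n_dual=2,
        )


@dataclass
class GroundTruth:
    """Ledger of every planted quantity, for recovery tests.

    ``lfc`` is keyed by the treatment-coded contrast column name the
    differential module produces (e.g. ``"c9_status[POS]"``), so planted and
    estimated fold changes share a sign convention.
    """

    region_table: pd.DataFrame  # chrom, start, end, region_id, class, base_log2
    gene_table: pd.DataFrame
    lfc: dict[str, np.ndarray]
    frip_coefs: np.ndarray
    batch_effects: pd.DataFrame | None
    size_factors: np.ndarray
    dispersions: np.ndarray
    driver_region_ids: list[str]
    driver_coefs: np.ndarray
    slope_signal: pd.Series
    slope_noise_sd: float
    links: pd.DataFrame  # gene_id, region_id, slope
    corr_outlier_ids: list[str]
    iqr_outlier_ids: list[str]
    small_batch_ids: list[str]

    def region_ids_of_class(self, cls: str) -> list[str]:
        t = self.region_table
        return t.loc[t["class"] == cls, "region_id"].tolist()

    def planted_r2(self) -> float:
        """Fraction of slope variance explained by the planted driver signal."""
        sig = self.slope_signal.dropna().to_numpy()
        v = float(np.var(sig))
        return v / (v + self.slope_noise_sd**2)


@dataclass
class SyntheticCohort:
    """Everything one simulated cohort produces."""

    config: CohortConfig
    seed: int
    metadata: pd.DataFrame
    regions: RegionSet
    genes: list[GeneRecord]
    counts: CountsMatrix
    expression: pd.DataFrame  # genes x expression samples
    truth: GroundTruth


# ---------------------------------------------------------------------------
# region / gene catalog


def build_region_catalog(config: CohortConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministically lay out regions and genes.

    Genes sit every 40 kb along chr1-chr5; each carries two promoter-proximal
    regions (centers within 2 kb of the TSS) and one distal region 20 kb
    downstream.  Special-effect blocks live on dedicated chromosomes (chr6
    sex-autosomal, chr9 C9-like, chr14 TCR-like, chr17 ancestry, chrX, chrY);
    technical/filler regions fill spare slots between genes.
    """
    rng = stream(seed, "regions")
    rows: list[dict] = []
    genes: list[dict] = []

    def add(chrom: str, start: int, cls: str, width: int | None = None) -> None:
        width = int(width if width is not None else rng.integers(300, 1200))
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(start + width),
                "class": cls,
            }
        )

    per_chrom = int(np.ceil(config.n_genes / len(_CHROMS_AUTOSOMAL)))
    extra_offsets = [8_000, 28_000]  # spare slots, far from every TSS
    spare: list[tuple[str, int]] = []
    g = 0
    for chrom in _CHROMS_AUTOSOMAL:
        for k in range(per_chrom):
            if g >= config.n_genes:
                break
            pos = 100_000 + _GENE_SPACING * k
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append({"gene_id": f"g{g:05d}", "chrom": chrom, "tss": pos, "strand": strand})
            add(chrom, pos - 700, "promoter", width=1200)  # center pos - 100
            add(chrom, pos + 800, "promoter", width=800)  # center pos + 1200
            add(chrom, pos + 19_600, "distal", width=800)
            for off in extra_offsets:
                spare.append((chrom, pos + off))
            g += 1

    def take_spare(n: int, cls: str) -> None:
        for _ in range(n):
            chrom, pos = spare.pop(0)
            add(chrom, pos, cls)

    # technical / biological blocks on shared autosomes
    take_spare(config.n_pbmc_memory, "pbmc_memory")
    take_spare(config.n_case_effect, "case_effect")
    take_spare(config.n_sequencer_effect, "sequencer_effect")
    take_spare(config.n_frip_effect, "frip_effect")
    take_spare(config.n_batch_effect, "batch_effect")
    take_spare(config.n_filler, "filler")

    # dedicated-chromosome blocks
    for i in range(config.n_sex_autosomal):
        add("chr6", 100_000 + 20_000 * i, "sex_autosomal")
    for i in range(config.n_c9):
        add("chr9", 100_000 + 20_000 * i, "c9")
    for i in range(config.n_tcr):
        add("chr14", 100_000 + 20_000 * i, "tcr")
    for i in range(config.n_ancestry):
        add("chr17", 100_000 + 20_000 * i, "ancestry")
    for i in range(config.n_xist):
        add("chrX", 100_000 + 20_000 * i, "xist")
    for i in range(config.n_chrx):
        add("chrX", 1_000_000 + 20_000 * i, "chrx")
    for i in range(config.n_chry):
        add("chrY", 100_000 + 20_000 * i, "chry")

    region_table = pd.DataFrame(rows)
    region_table = region_table.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    region_table["region_id"] = [f"r{i:05d}" for i in range(len(region_table))]
    gene_table = pd.DataFrame(genes)
    return region_table, gene_table


def _catalog_to_objects(
    region_table: pd.DataFrame, gene_table: pd.DataFrame
) -> tuple[RegionSet, list[GeneRecord]]:
    regions = RegionSet(
        [
            GenomicRegion(r.chrom, r.start, r.end, r.region_id)
            for r in region_table.itertuples()
        ]
    )
    genes = [
        GeneRecord(r.gene_id, r.chrom, int(r.tss), r.strand) for r in gene_table.itertuples()
    ]
    return regions, genes


# ---------------------------------------------------------------------------
# metadata


def _exact_split(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with exactly round(fraction * n) True entries, randomly placed."""
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


def simulate_metadata(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Generate the per-sample covariate table.

    Group counts match the configuration exactly.  ALSFRS-R slopes are
    filled in a second pass (see :func:`simulate_cohort`) because the
    progression signal is linear in measured accessibility; here slope
    columns carry only the eligibility pattern (NaN for controls and for
    cases without a recorded slope).
    """
    config.validate()
    rng = stream(seed, "metadata")
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    case_status = np.array(["ALS"] * config.n_cases + ["HC"] * config.n_controls)
    case_status = case_status[rng.permutation(n)]
    is_case = case_status == "ALS"

    sex = np.where(_exact_split(rng, n, config.female_fraction), "Female", "Male")
    pbmc = np.where(_exact_split(rng, n, config.tcell_fraction), "T-cell", "non-T-cell").astype(object)
    pbmc[_exact_split(rng, n, config.pbmc_missing_fraction)] = np.nan
    ancestry = np.where(_exact_split(rng, n, config.afr_fraction), "AFR", "EUR")
    sequencer = np.where(
        _exact_split(rng, n, config.novaseq_fraction), "NovaSeq6000", "HiSeq4000"
    )
    frip = np.clip(
        rng.normal(config.frip_mean, config.frip_sd, size=n), 0.05, 0.6
    )

    case_idx = np.flatnonzero(is_case)

    # slope eligibility: controls and a few cases have no recorded slope
    has_slope = is_case.copy()
    no_slope = rng.permutation(case_idx)[: config.n_missing_slope_cases]
    has_slope[no_slope] = False

    # planted predictor-filter pathologies among slope-carrying cases
    w_idx = rng.permutation(np.flatnonzero(has_slope))
    corr_out = w_idx[: config.n_corr_outliers]
    iqr_out = w_idx[config.n_corr_outliers : config.n_corr_outliers + config.n_iqr_outliers]
    k0 = config.n_corr_outliers + config.n_iqr_outliers
    small_batch = w_idx[k0 : k0 + config.n_small_batch_samples]
    retained = w_idx[k0 + config.n_small_batch_samples :]

    # verified C9 groups are planted among QC-passing cases, so the analyzed
    # contrast sees exactly the configured group sizes
    c9_pool = rng.permutation(np.setdiff1d(case_idx, corr_out))
    c9 = np.full(n, np.nan, dtype=object)
    c9[c9_pool[: config.c9_pos]] = "POS"
    c9[c9_pool[config.c9_pos : config.c9_pos + config.c9_neg]] = "NEG"

    batch = np.empty(n, dtype=object)
    n_small_batches = config.n_small_batch_samples // config.small_batch_size
    for b in range(n_small_batches):
        sl = small_batch[b * config.small_batch_size : (b + 1) * config.small_batch_size]
        batch[sl] = f"batch_s{b:02d}"
    n_main = int(np.ceil(len(retained) / config.main_batch_size))
    for b in range(n_main):
        sl = retained[b * config.main_batch_size : (b + 1) * config.main_batch_size]
        batch[sl] = f"batch_m{b:02d}"
    others = np.flatnonzero(pd.isna(pd.Series(batch)))
    for k, j in enumerate(others):
        batch[j] = f"batch_m{k % max(n_main, 1):02d}"

    onset = np.where(is_case, np.round(np.exp(rng.normal(0.7, 0.5, size=n)), 2), np.nan)

    # depth factors drive total reads; counts use the identical stream
    s_true = 2.0 ** stream(seed, "depth").uniform(*config.depth_log2_range, size=n)
    rng_reads = stream(seed, "reads")
    total = np.round(
        config.mean_total_reads * s_true * np.exp(rng_reads.normal(0, 0.05, size=n))
    )
    x_in_peaks = np.round(
        total * config.peak_x_rate * np.exp(rng_reads.normal(0, config.rnip_noise_sd, size=n))
    )
    bg_rate = np.where(
        sex == "Female",
        config.rnip_male_rate * config.rnip_female_ratio,
        config.rnip_male_rate,
    )
    bg = np.round(total * bg_rate * np.exp(rng_reads.normal(0, config.rnip_noise_sd, size=n)))
    chrx = x_in_peaks + bg

    table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sex,
            "pbmc_type": pbmc,
            "sequencer": sequencer,
            "frip": frip,
            "diff_batch": batch,
            "ancestry": ancestry,
            "case_status": case_status,
            "c9_status": c9,
            "alsfrs_r_slope": np.where(has_slope, 0.0, np.nan),
            "onset_to_collection_years": onset,
            "total_reads": total.astype(np.int64),
            "chrx_reads": chrx.astype(np.int64),
            "chrx_reads_in_peaks": x_in_peaks.astype(np.int64),
        }
    )
    table.attrs["corr_outlier_ids"] = [sample_ids[i] for i in corr_out]
    table.attrs["iqr_outlier_ids"] = [sample_ids[i] for i in iqr_out]
    table.attrs["small_batch_ids"] = [sample_ids[i] for i in small_batch]
    return validate_sample_table(table)


# ---------------------------------------------------------------------------
# counts


def _pick(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    return rng.choice(pool, size=k, replace=False)


def simulate_counts(
    config: CohortConfig, metadata: pd.DataFrame, seed: int
) -> tuple[CountsMatrix, GroundTruth]:
    """Draw the region x sample NB counts matrix and record the ground truth.

    ``K_ij ~ NB(mean = s_j * q_ij, dispersion = alpha_i)`` with
    ``log2 q_ij = b_i + sum of planted effects`` evaluated on sample ``j``'s
    covariates, and ``alpha_i`` scattered log-normally around the trend
    ``a1 / mu + alpha0``.
    """
    config.validate()
    region_table, gene_table = build_region_catalog(config, seed)
    n_regions, n = len(region_table), config.n_samples
    rng = stream(seed, "counts")

    cls = region_table["class"].to_numpy()
    base = rng.uniform(*config.base_log2_mean_range, size=n_regions)
    promoter_like = np.isin(cls, ["promoter", "c9"])  # c9 block models a TSS
    base[promoter_like] = np.clip(
        base[promoter_like] + config.promoter_log2_boost,
        None,
        config.base_log2_mean_range[1] + config.promoter_log2_boost,
    )
    region_table = region_table.assign(base_log2=base)

    female = (metadata["sex"] == "Female").to_numpy(dtype=float)
    tcell = (metadata["pbmc_type"] == "T-cell").to_numpy(dtype=float)
    afr = (metadata["ancestry"] == "AFR").to_numpy(dtype=float)
    novaseq = (metadata["sequencer"] == "NovaSeq6000").to_numpy(dtype=float)
    als = (metadata["case_status"] == "ALS").to_numpy(dtype=float)
    c9pos = (metadata["c9_status"] == "POS").to_numpy(dtype=float)
    frip_c = metadata["frip"].to_numpy(dtype=float) - config.frip_mean

    # per-region planted log2 effects, keyed by covariate indicator
    female_eff = np.zeros(n_regions)
    tcell_eff = np.zeros(n_regions)
    afr_eff = np.zeros(n_regions)
    novaseq_eff = np.zeros(n_regions)
    als_eff = np.zeros(n_regions)
    c9_eff = np.zeros(n_regions)
    frip_eff = np.zeros(n_regions)

    female_eff[cls == "chry"] = config.lfc_chry_female
    female_eff[cls == "xist"] = config.lfc_xist_female
    sgn = rng.choice([-1.0, 1.0], size=(cls == "sex_autosomal").sum())
    female_eff[cls == "sex_autosomal"] = config.lfc_sex_autosomal * sgn
    tcell_eff[cls == "tcr"] = config.lfc_tcr_tcell
    mem = cls == "pbmc_memory"
    tcell_eff[mem] = config.lfc_pbmc_memory * rng.choice([-1.0, 1.0], size=mem.sum()) * rng.uniform(
        0.6, 1.25, size=mem.sum()
    )
    anc = cls == "ancestry"
    # a minority of ancestry regions more accessible in AFR, the rest less
    anc_sign = np.where(np.arange(anc.sum()) < max(1, anc.sum() // 3), 1.0, -1.0)
    afr_eff[anc] = config.lfc_ancestry * anc_sign
    c9_eff[cls == "c9"] = config.lfc_c9
    ce = cls == "case_effect"
    als_eff[ce] = config.lfc_case * rng.choice([-1.0, 1.0], size=ce.sum())
    se = cls == "sequencer_effect"
    novaseq_eff[se] = config.lfc_sequencer * rng.choice([-1.0, 1.0], size=se.sum())
    fe = cls == "frip_effect"
    frip_eff[fe] = config.frip_coef * rng.choice([-1.0, 1.0], size=fe.sum())

    log2q = (
        base[:, None]
        + np.outer(female_eff, female)
        + np.outer(tcell_eff, np.nan_to_num(tcell))
        + np.outer(afr_eff, afr)
        + np.outer(novaseq_eff, novaseq)
        + np.outer(als_eff, als)
        + np.outer(c9_eff, c9pos)
        + np.outer(frip_eff, frip_c)
    )

    batch_effects = None
    be = cls == "batch_effect"
    if be.any():
        batches = sorted(metadata["diff_batch"].unique())
        shifts = rng.normal(0, config.batch_effect_sd, size=(be.sum(), len(batches)))
        bidx = metadata["diff_batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
        log2q[be] += shifts[:, bidx]
        batch_effects = pd.DataFrame(
            shifts, index=region_table.loc[be, "region_id"], columns=batches
        )

    # decorrelated samples: their region profile is a permutation of the
    # baseline, so they share no mean structure with the rest of the cohort
    corr_ids = metadata.attrs.get("corr_outlier_ids", [])
    sample_ids = metadata["sample_id"].tolist()
    for sid in corr_ids:
        j = sample_ids.index(sid)
        log2q[:, j] = base[rng.permutation(n_regions)]

    s_true = 2.0 ** stream(seed, "depth").uniform(*config.depth_log2_range, size=n)
    mu = s_true[None, :] * 2.0**log2q
    mu_region = 2.0**base  # trend anchored at the baseline mean
    alpha = (config.a1 / mu_region + config.alpha0) * np.exp(
        rng.normal(0, config.dispersion_scatter_sd, size=n_regions)
    )
    alpha = np.clip(alpha, 1e-8, 10.0)
    r = 1.0 / alpha
    counts = rng.negative_binomial(r[:, None], r[:, None] / (r[:, None] + mu))

    counts_matrix = CountsMatrix(
        counts.astype(np.int64), region_table["region_id"].tolist(), sample_ids
    )
    lfc = {
        "sex[Male]": -female_eff,
        "pbmc_type[non-T-cell]": -tcell_eff,
        "ancestry[EUR]": -afr_eff,
        "sequencer[NovaSeq6000]": novaseq_eff,
        "case_status[HC]": -als_eff,
        "c9_status[POS]": c9_eff,
    }
    truth = GroundTruth(
        region_table=region_table,
        gene_table=gene_table,
        lfc=lfc,
        frip_coefs=frip_eff,
        batch_effects=batch_effects,
        size_factors=s_true,
        dispersions=alpha,
        driver_region_ids=[],
        driver_coefs=np.array([]),
        slope_signal=pd.Series(np.nan, index=sample_ids),
        slope_noise_sd=config.slope_noise_sd,
        links=pd.DataFrame(columns=["gene_id", "region_id", "slope"]),
        corr_outlier_ids=list(corr_ids),
        iqr_outlier_ids=list(metadata.attrs.get("iqr_outlier_ids", [])),
        small_batch_ids=list(metadata.attrs.get("small_batch_ids", [])),
    )
    return counts_matrix, truth


def _assign_slopes(
    config: CohortConfig,
    metadata: pd.DataFrame,
    counts: CountsMatrix,
    truth: GroundTruth,
    seed: int,
) -> pd.DataFrame:
    """Second pass: ALSFRS-R slope linear in measured driver accessibility."""
    rng = stream(seed, "slopes")
    promoters = truth.region_ids_of_class("promoter")
    drivers = sorted(rng.choice(promoters, size=config.n_drivers, replace=False))
    coefs = rng.choice([-1.0, 1.0], size=config.n_drivers) * rng.uniform(
        0.8, 1.2, size=config.n_drivers
    )
    coefs *= config.driver_signal_sd / np.linalg.norm(coefs)

    sub = counts.subset_regions(drivers)
    acc = np.log2(sub.values / truth.size_factors[None, :] + 1.0)
    has_slope = metadata["alsfrs_r_slope"].notna().to_numpy()
    pathological = set(truth.corr_outlier_ids) | set(truth.iqr_outlier_ids)
    ref = has_slope & ~metadata["sample_id"].isin(pathological).to_numpy()
    mean = acc[:, ref].mean(axis=1, keepdims=True)
    sd = acc[:, ref].std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (acc - mean) / sd

    signal = config.slope_mean + coefs @ z
    noise = rng.normal(0, config.slope_noise_sd, size=len(signal))
    slope = signal + noise

    metadata = metadata.copy()
    slope_col = np.where(has_slope, np.round(slope, 4), np.nan)
    # extreme-slope samples sit far outside the 1.5-IQR fences by design
    sample_ids = metadata["sample_id"].tolist()
    for k, sid in enumerate(truth.iqr_outlier_ids):
        j = sample_ids.index(sid)
        offset = (3.5 + 0.5 * k) * (1 if k % 2 else -1)
        slope_col[j] = np.round(config.slope_mean + offset, 4)
    metadata["alsfrs_r_slope"] = slope_col

    truth.driver_region_ids = list(drivers)
    truth.driver_coefs = coefs
    truth.slope_signal = pd.Series(
        np.where(ref, signal, np.nan), index=sample_ids
    )
    return metadata


# ---------------------------------------------------------------------------
# expression


def _candidate_regions_for_gene(
    gene: pd.Series, region_table: pd.DataFrame, window: int
) -> pd.DataFrame:
    t = region_table
    center = (t["start"] + t["end"]) // 2
    on = (t["chrom"] == gene["chrom"]) & ((center - gene["tss"]).abs() <= window)
    return t[on]


def simulate_expression(
    config: CohortConfig,
    counts: CountsMatrix,
    truth: GroundTruth,
    metadata: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Gene x sample expression with planted cis links to accessibility.

    For linked pairs, expression is ``slope x (standardized log accessibility)``
    plus Gaussian noise; a few dual-sign peaks are linked to two genes with
    opposite signs; all other genes are covariate-tinged noise.  Expression
    is reported for a random subset of samples (matched-assay subcohort).
    """
    rng = stream(seed, "expression")
    n = config.n_samples
    n_expr = int(round(config.expr_sample_fraction * n))
    expr_samples = sorted(rng.choice(counts.sample_ids, size=n_expr, replace=False))
    sub = counts.subset_samples(expr_samples)
    meta = metadata.set_index("sample_id").loc[expr_samples]

    genes = truth.gene_table
    baseline = rng.normal(6.0, 1.0, size=len(genes))
    E = np.tile(baseline[:, None], (1, n_expr)).astype(float)
    E += rng.normal(0, config.expr_noise_sd, size=E.shape)

    # mild covariate structure removed downstream by residualization
    female = (meta["sex"] == "Female").to_numpy(dtype=float)
    frip_c = meta["frip"].to_numpy(dtype=float) - config.frip_mean
    E += np.outer(rng.normal(0, 0.2, size=len(genes)), female)
    E += np.outer(rng.normal(0, 1.0, size=len(genes)), frip_c)

    s_expr = truth.size_factors[[counts.sample_ids.index(s) for s in expr_samples]]

    def z_of(region_id: str) -> np.ndarray:
        i = sub.region_ids.index(region_id)
        a = np.log2(sub.values[i] / s_expr + 1.0)
        sd = a.std() or 1.0
        return (a - a.mean()) / sd

    gene_ids = genes["gene_id"].tolist()
    pool = rng.permutation(len(genes))
    links: list[dict] = []

    def plant(gidx: int, region_id: str, slope: float) -> None:
        E[gidx] += slope * z_of(region_id)
        links.append({"gene_id": gene_ids[gidx], "region_id": region_id, "slope": slope})

    used = 0
    lo, hi = config.link_slope_range
    for k in range(config.n_links):
        gidx = pool[used]
        used += 1
        gene = genes.iloc[gidx]
        cands = _candidate_regions_for_gene(gene, truth.region_table, config.coexpr_window)
        distal = cands[cands["class"] != "promoter"]
        pick_from = distal if len(distal) else cands
        region_id = str(pick_from.iloc[int(rng.integers(len(pick_from)))]["region_id"])
        sign = -1.0 if rng.random() < config.link_negative_fraction else 1.0
        plant(gidx, region_id, float(sign * rng.uniform(lo, hi)))

    for k in range(config.n_dual):
        g1, g2 = pool[used], pool[used + 1]
        used += 2
        gene1 = genes.iloc[g1]
        cands = _candidate_regions_for_gene(gene1, truth.region_table, config.coexpr_window)
        # a region cis to both genes: prefer one within the window of g2 too
        center = (cands["start"] + cands["end"]) // 2
        tss2 = genes.iloc[g2]["tss"]
        both = cands[
            (cands["chrom"] == genes.iloc[g2]["chrom"])
            & ((center - tss2).abs() <= config.coexpr_window)
        ]
        pick_from = both if len(both) else cands
        region_id = str(pick_from.iloc[int(rng.integers(len(pick_from)))]["region_id"])
        mag1, mag2 = rng.uniform(lo, hi, size=2)
        plant(g1, region_id, float(mag1))
        plant(g2, region_id, float(-mag2))

    link_table = pd.DataFrame(links, columns=["gene_id", "region_id", "slope"])
    known_regions = set(truth.region_table["region_id"])
    bad = set(link_table["region_id"]) - known_regions
    if bad:
        raise ValueError(f"links reference unknown regions: {sorted(bad)[:3]}")
    truth.links = link_table
    return pd.DataFrame(E, index=gene_ids, columns=expr_samples)


# ---------------------------------------------------------------------------
# per-sample peak sets (for the consensus stage)


def simulate_peaks(
    config: CohortConfig,
    regions: RegionSet,
    seed: int,
) -> list[RegionSet]:
    """Per-sample peak calls: every true region is open in 30-95% of samples,
    decoy regions in ~3%, so a 10% consensus threshold keeps exactly the true
    catalog.  Boundaries are jittered by up to 50 bp per sample."""
    rng = stream(seed, "peaks")
    n = config.n_samples
    true_regions = list(regions)
    open_prob = rng.uniform(0.3, 0.95, size=len(true_regions))
    decoys = [
        GenomicRegion("chr20", 100_000 + 20_000 * i, 100_000 + 20_000 * i + 600, f"decoy{i:03d}")
        for i in range(config.n_decoy)
    ]
    out: list[RegionSet] = []
    for j in range(n):
        regs: list[GenomicRegion] = []
        opened = rng.random(len(true_regions)) < open_prob
        for i, r in enumerate(true_regions):
            if not opened[i]:
                continue
            j1, j2 = rng.integers(-50, 51, size=2)
            start = max(0, r.start + int(j1))
            end = max(start + 50, r.end + int(j2))
            regs.append(GenomicRegion(r.chrom, start, end, f"{r.region_id}_s{j}"))
        for d in decoys:
            if rng.random() < 0.03:
                regs.append(GenomicRegion(d.chrom, d.start, d.end, f"{d.region_id}_s{j}"))
        out.append(RegionSet(regs))
    return out


# ---------------------------------------------------------------------------
# orchestration


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort (metadata, counts, expression, truth).

    Slope assignment is a second pass over the realized counts so the
    progression signal is exactly linear in measured driver accessibility.
    """
    config = (config or CohortConfig()).validate()
    metadata = simulate_metadata(config, seed)
    counts, truth = simulate_counts(config, metadata, seed)
    metadata = _assign_slopes(config, metadata, counts, truth, seed)
    expression = simulate_expression(config, counts, truth, metadata, seed)
    regions, genes = _catalog_to_objects(truth.region_table, truth.gene_table)
    return SyntheticCohort(config, seed, metadata, regions, genes, counts, expression, truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the fixture bundle (all plain text) plus the ground-truth ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sample_table(cohort.metadata, outdir / "metadata.tsv")
    write_regions_bed(cohort.regions, outdir / "regions.bed")
    write_gene_table(cohort.genes, outdir / "genes.tsv")
    write_counts_tsv(cohort.counts, outdir / "counts.tsv")
    cohort.expression.rename_axis("gene_id").to_csv(outdir / "expression.tsv", sep="\t")

    truth = cohort.truth
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    truth.region_table.to_csv(tdir / "regions.tsv", sep="\t", index=False)
    lfc = pd.DataFrame(truth.lfc, index=truth.region_table["region_id"])
    lfc.rename_axis("region_id").to_csv(tdir / "lfc.tsv", sep="\t")
    pd.DataFrame(
        {"region_id": truth.driver_region_ids, "coef": truth.driver_coefs}
    ).to_csv(tdir / "drivers.tsv", sep="\t", index=False)
    truth.links.to_csv(tdir / "links.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": cohort.counts.sample_ids,
            "size_factor": truth.size_factors,
            "slope_signal": truth.slope_signal.to_numpy(),
            "corr_outlier": [s in set(truth.corr_outlier_ids) for s in cohort.counts.sample_ids],
            "iqr_outlier": [s in set(truth.iqr_outlier_ids) for s in cohort.counts.sample_ids],
            "small_batch": [s in set(truth.small_batch_ids) for s in cohort.counts.sample_ids],
        }
    ).to_csv(tdir / "samples.tsv", sep="\t", index=False)
    meta = {
        "seed": cohort.seed,
        "slope_noise_sd": truth.slope_noise_sd,
        "planted_r2": truth.planted_r2(),
        "config": dataclasses.asdict(cohort.config),
    }
    (tdir / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
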