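"""Stage orchestration for the synthetic-to-report workflow.

Each stage reads its inputs from the artifacts directory written by earlier
stages and writes plain-text outputs (TSV/JSON/BED), so any stage can be
rerun or inspected in isolation.  A structured ``key=value`` log line per
stage goes to stderr.  All randomness derives from the config's master seed
via named streams.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rand import child_seed
from .coexpression import map_all_pairs
from .differential import run_differential
from .io import TransformedMatrix, read_counts_tsv, read_sample_table
from .normalization import (
    estimate_dispersions,
    size_factors_median_of_ratios,
    vst,
)
from .progression import run_progression
from .qc import chrx_rnip, impute_pbmc_labels, inter_sample_correlation_cluster, pca, top_variable_regions
from .regions import build_consensus, read_gene_table, read_regions_bed, write_regions_bed
from .simulate import CohortConfig, simulate_cohort, simulate_peaks, write_cohort
from .varpart import VarParSpec, partition_matrix, summarize_fractions

__all__ = ["PipelineConfig", "run_subcommand", "STAGES"]


@dataclass
class PipelineConfig:
    """Numeric conventions and paths for the whole workflow."""

    outdir: str = "artifacts"
    master_seed: int = 0
    cohort_scale: str = "desk"  # "desk" or "tiny"
    consensus_min_fraction: float = 0.10
    promoter_halfwidth: int = 2_000
    top_variable: int = 500
    varpart_max_regions: int = 500
    diff_adj_p: float = 0.01
    diff_min_abs_lfc: float = 0.5
    diff_sex_min_abs_lfc: float = 1.0
    coexpr_window: int = 250_000
    coexpr_alpha: float = 0.01
    coexpr_proximal: int = 2_500
    progression_n_folds: int = 10
    progression_n_runs: int = 1000
    progression_min_per_batch: int = 4
    progression_iqr_multiplier: float = 1.5
    progression_test_fraction: float = 0.1
    progression_majority_threshold: float = 0.5
    progression_majority_denominator: str = "all"
    progression_lambda_rule: str = "min"
    impute_k: int = 15

    def validate(self) -> "PipelineConfig":
        if not (0 < self.consensus_min_fraction <= 1):
            raise ValueError("consensus_min_fraction must lie in (0, 1]")
        if self.cohort_scale not in {"desk", "tiny"}:
            raise ValueError("cohort_scale must be 'desk' or 'tiny'")
        if not (0 < self.diff_adj_p < 1) or not (0 < self.coexpr_alpha < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.progression_majority_denominator not in {"all", "nonempty"}:
            raise ValueError("majority denominator must be 'all' or 'nonempty'")
        if self.progression_lambda_rule not in {"min", "1se"}:
            raise ValueError("lambda rule must be 'min' or '1se'")
        return self

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def cohort_config(self) -> CohortConfig:
        return CohortConfig.tiny() if self.cohort_scale == "tiny" else CohortConfig()


def _log(stage: str, t0: float, **kv) -> None:
    extras = " ".join(f"{k}={v}" for k, v in kv.items())
    print(f"stage={stage} wall_s={time.time() - t0:.1f} {extras}", file=sys.stderr)


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{producer}' subcommand first"
        )
    return path


def _read_vst(out: Path) -> TransformedMatrix:
    df = pd.read_csv(_require(out / "vst.tsv", "normalize"), sep="\t", index_col=0)
    return TransformedMatrix.from_frame(df)


def stage_simulate(config: PipelineConfig) -> None:
    t0 = time.time()
    out = _outdir(config)
    seed = child_seed(config.master_seed, "cohort")
    cohort = simulate_cohort(config.cohort_config(), seed=seed)
    write_cohort(cohort, out)
    peaks = simulate_peaks(cohort.config, cohort.regions, seed=seed)
    pdir = out / "peaks"
    pdir.mkdir(exist_ok=True)
    for sid, ps in zip(cohort.counts.sample_ids, peaks):
        write_regions_bed(ps, pdir / f"{sid}.bed")
    _log("simulate", t0, seed=seed, n_samples=cohort.counts.n_samples, n_regions=cohort.counts.n_regions)


def stage_consensus(config: PipelineConfig) -> None:
    t0 = time.time()
    out = _outdir(config)
    pdir = _require(out / "peaks", "simulate")
    peak_sets = [read_regions_bed(p) for p in sorted(pdir.glob("*.bed"))]
    cons = build_consensus(peak_sets, min_fraction=config.consensus_min_fraction)
    write_regions_bed(cons, out / "consensus.bed")
    _log("consensus", t0, n_in=len(peak_sets), n_out=len(cons))


def stage_normalize(config: PipelineConfig) -> None:
    t0 = time.time()
    out = _outdir(config)
    counts = read_counts_tsv(_require(out / "counts.tsv", "simulate"))
    sf = size_factors_median_of_ratios(counts)
    dm = estimate_dispersions(counts, sf)
    tm = vst(counts, sf, dm)
    pd.DataFrame({"sample_id": sf.sample_ids, "size_factor": sf.s}).to_csv(
        out / "size_factors.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"region_id": dm.region_ids, "mu_hat": dm.mu_hat, "alpha_hat": dm.alpha_hat}
    ).to_csv(out / "dispersions.tsv", sep="\t", index=False)
    (out / "dispersion_trend.json").write_text(
        json.dumps({"alpha0": dm.alpha0, "a1": dm.a1}, indent=2)
    )
    vdf = tm.to_frame()
    vdf.index.name = "region_id"
    vdf.round(6).to_csv(out / "vst.tsv", sep="\t")
    _log("normalize", t0, n_regions=counts.n_regions, alpha0=round(dm.alpha0, 4), a1=round(dm.a1, 3))


def stage_qc(config: PipelineConfig) -> None:
    t0 = time.time()
    out = _outdir(config)
    tm = _read_vst(out)
    meta = read_sample_table(_require(out / "metadata.tsv", "simulate"))
    top = top_variable_regions(tm, min(config.top_variable, tm.n_regions))
    res = pca(tm, top, n_components=5)
    res.scores.rename_axis("sample_id").to_csv(out / "pca_scores.tsv", sep="\t")
    completed = impute_pbmc_labels(tm, meta, k=min(config.impute_k, tm.n_samples // 2))
    completed.rename("pbmc_type_imputed").rename_axis("sample_id").to_csv(
        out / "imputed_pbmc.tsv", sep="\t"
    )
    rnip = chrx_rnip(meta)
    rnip.per_sample.to_csv(out / "rnip.tsv", sep="\t", index=False)
    cluster = inter_sample_correlation_cluster(tm)
    summary = {
        "pca_variance_fractions": [float(v) for v in res.variance_fractions],
        "n_imputed_pbmc": int(meta["pbmc_type"].isna().sum()),
        "rnip_median_female": float(rnip.group_medians.get("Female", np.nan)),
        "rnip_median_male": float(rnip.group_medians.get("Male", np.nan)),
        "rnip_mannwhitney_p": rnip.mannwhitney_p,
        "correlation_outliers": cluster.flagged_sample_ids,
    }
    (out / "qc_summary.json").write_text(json.dumps(summary, indent=2))
    _log("qc", t0, n_top=len(top), n_imputed=summary["n_imputed_pbmc"])


_VARPART_RANDOM = ["diff_batch", "sequencer", "sex", "case_status", "pbmc_type", "ancestry"]
_VARPART_FIXED = ["frip"]


def stage_varpart(config: PipelineConfig) -> None:
    t0 = time.time()
    out = _outdir(config)
    tm = _read_vst(out)
    meta = read_sample_table(_require(out / "metadata.tsv", "simulate"))
    imputed = out / "imputed_pbmc.tsv"
    if imputed.exists():
        lab = pd.read_csv(imputed, sep="\t").set_index("sample_id")["pbmc_type_imputed"]
        meta = meta.assign(pbmc_type=lab.reindex(meta["sample_id"]).to_numpy())
    meta = meta.dropna(subset=["pbmc_type"])
    tm = tm.subset_samples([s for s in tm.sample_ids if s in set(meta["sample_id"])])
    rng = np.random.default_rng(child_seed(config.master_seed, "varpart"))
    n_use = min(config.varpart_max_regions, tm.n_regions)
    rows = sorted(rng.choice(tm.n_regions, size=n_use, replace=False).tolist())
    sub = tm.subset_regions([tm.region_ids[i] for i in rows])
    spec = VarParSpec(list(_VARPART_RANDOM), list(_VARPART_FIXED))
    fractions = partition_matrix(sub.values, sub.region_ids, meta, spec)
    fractions.round(6).to_csv(out / "varpart.tsv", sep="\t")
    summarize_fractions(fractions).round(6).to_csv(out / "varpart_summary.tsv", sep="\t")
    _log("varpart", t0, n_regions=n_use)


_DIFF_COVARIATES = ["frip", "sequencer", "sex", "pbmc_type", "case_status"]

#: contrast -> (covariates, min_abs_lfc override or None)
_CONTRASTS = {
    "sex": ([c for c in _DIFF_COVARIATES if c != "sex"], "sex"),
    "pbmc_type": ([c for c in _DIFF_COVARIATES if c != "pbmc_type"], None),
    "ancestry": (_DIFF_COVARIATES, None),
    "case_status": ([c for c in _DIFF_COVARIATES if c != "case_status"], None),
    "c9_status": ([c for c in _DIFF_COVARIATES if c != "case_status"], None),
}


def stage_diff(config: PipelineConfig) -> None:
    t0 = time.time()
    out = _outdir(config)
    counts = read_counts_tsv(_require(out / "counts.tsv", "simulate"))
    meta = read_sample_table(_require(out / "metadata.tsv", "simulate"))
    imputed = out / "imputed_pbmc.tsv"
    if imputed.exists():
        lab = pd.read_csv(imputed, sep="\t").set_index("sample_id")["pbmc_type_imputed"]
        meta = meta.assign(pbmc_type=lab.reindex(meta["sample_id"]).to_numpy())
    qc_summary = out / "qc_summary.json"
    if qc_summary.exists():
        # decorrelated samples violate the count model in every region;
        # drop the QC-flagged ones before model-based testing
        flagged = set(json.loads(qc_summary.read_text()).get("correlation_outliers", []))
        if flagged:
            keep = [s for s in counts.sample_ids if s not in flagged]
            counts = counts.subset_samples(keep)
            meta = meta[meta["sample_id"].isin(keep)].reset_index(drop=True)
    sf = size_factors_median_of_ratios(counts)
    dm = estimate_dispersions(counts, sf)
    n_dars = {}
    for contrast, (covs, lfc_override) in _CONTRASTS.items():
        min_lfc = config.diff_sex_min_abs_lfc if lfc_override == "sex" else config.diff_min_abs_lfc
        res = run_differential(
            counts,
            meta,
            contrast=contrast,
            covariates=covs,
            adj_p_threshold=config.diff_adj_p,
            min_abs_log2fc=min_lfc,
            size_factors=sf,
            dispersion=dm,
        )
        res.table.round(6).to_csv(out / f"diff_{contrast}.tsv", sep="\t", index=False)
        n_dars[contrast] = len(res.dar_ids)
    (out / "diff_summary.json").write_text(json.dumps(n_dars, indent=2))
    _log("diff", t0, **{f"dars_{k}": v for k, v in n_dars.items()})


def stage_progression(config: PipelineConfig) -> None:
    t0 = time.time()
    out = _outdir(config)
    tm = _read_vst(out)
    meta = read_sample_table(_require(out / "metadata.tsv", "simulate"))
    regions = read_regions_bed(_require(out / "regions.bed", "simulate"))
    genes = read_gene_table(_require(out / "genes.tsv", "simulate"))
    res = run_progression(
        tm,
        meta,
        regions,
        genes,
        tss_halfwidth=config.promoter_halfwidth,
        iqr_multiplier=config.progression_iqr_multiplier,
        min_per_batch=config.progression_min_per_batch,
        test_fraction=config.progression_test_fraction,
        n_runs=config.progression_n_runs,
        n_folds=config.progression_n_folds,
        master_seed=child_seed(config.master_seed, "progression"),
        majority_threshold=config.progression_majority_threshold,
        majority_denominator=config.progression_majority_denominator,
        lambda_rule=config.progression_lambda_rule,
    )
    rep = res.filter_report
    rows = (
        [(s, "excluded_correlation") for s in rep.excluded_by_correlation]
        + [(s, "excluded_slope_iqr") for s in rep.excluded_by_slope_iqr]
        + [(s, "excluded_batch") for s in rep.excluded_by_batch]
        + [(s, "retained_train") for s in res.train_ids]
        + [(s, "retained_test") for s in res.test_ids]
    )
    pd.DataFrame(rows, columns=["sample_id", "status"]).to_csv(
        out / "progression_filter.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "run_index": r.run_index,
                "lambda": r.lambda_chosen,
                "n_selected": len(r.selected_region_ids),
                "train_rmse": r.train_rmse,
                "train_r2": r.train_r2,
                "test_rmse": r.test_rmse,
                "test_r2": r.test_r2,
            }
            for r in res.stability.runs
        ]
    ).round(6).to_csv(out / "progression_runs.tsv", sep="\t", index=False)
    res.stability.selection_frequency.sort_values(ascending=False).round(4).to_csv(
        out / "progression_selection_frequency.tsv", sep="\t"
    )
    model = {
        "majority_set": res.stability.majority_set,
        "aggregate": {k: float(v) for k, v in res.stability.aggregate().items()},
    }
    if res.majority_model is not None:
        model["intercept"] = res.majority_model.intercept
        model["coefficients"] = dict(
            zip(res.majority_model.region_ids, map(float, res.majority_model.coefficients))
        )
        model["majority_metrics"] = res.majority_metrics
    (out / "progression_model.json").write_text(json.dumps(model, indent=2))
    _log(
        "progression",
        t0,
        retained=len(rep.retained),
        n_runs=config.progression_n_runs,
        majority=len(res.stability.majority_set),
    )


def stage_coexpr(config: PipelineConfig) -> None:
    t0 = time.time()
    out = _outdir(config)
    tm = _read_vst(out)
    meta = read_sample_table(_require(out / "metadata.tsv", "simulate"))
    regions = read_regions_bed(_require(out / "regions.bed", "simulate"))
    genes = read_gene_table(_require(out / "genes.tsv", "simulate"))
    expr = pd.read_csv(_require(out / "expression.tsv", "simulate"), sep="\t", index_col=0)
    res = map_all_pairs(
        expr,
        tm,
        genes,
        regions,
        meta,
        window=config.coexpr_window,
        alpha=config.coexpr_alpha,
        proximal_bp=config.coexpr_proximal,
    )
    res.pairs.round(6).to_csv(out / "coexpr_pairs.tsv", sep="\t", index=False)
    (out / "coexpr_summary.json").write_text(json.dumps(res.summary, indent=2))
    _log("coexpr", t0, n_pairs=res.summary["n_pairs_tested"], n_sig=res.summary["n_significant_pairs"])


STAGES = {
    "simulate": stage_simulate,
    "consensus": stage_consensus,
    "normalize": stage_normalize,
    "qc": stage_qc,
    "varpart": stage_varpart,
    "diff": stage_diff,
    "progression": stage_progression,
    "coexpr": stage_coexpr,
}

_ALL_ORDER = ["simulate", "consensus", "normalize", "qc", "varpart", "diff", "progression", "coexpr"]


def run_subcommand(name: str, config: PipelineConfig) -> None:
    """Run one stage (or 'all') against the configured artifacts directory."""
    config.validate()
    if name == "all":
        for stage in _ALL_ORDER:
            STAGES[stage](config)
        return
    if name not in STAGES:
        raise ValueError(f"unknown subcommand {name!r}; choose from {sorted(STAGES)} or 'all'")
    STAGES[name](config)
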