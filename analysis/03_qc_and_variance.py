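"""Cohort QC and per-region variance partitioning.

PCA on the most variably accessible regions, PBMC-label imputation in PC
space, the chrX reads-not-in-peaks statistic by sex (X-inactivation
background), the guarded inter-sample correlation cut, and REML variance
fractions for a subsample of regions against the cohort covariates.
"""

import json
from pathlib import Path

import pandas as pd

from config import analysis_config
from imnatac.pipeline import stage_qc, stage_varpart

config = analysis_config()
stage_qc(config)
stage_varpart(config)

out = Path(config.outdir)
qc = json.loads((out / "qc_summary.json").read_text())
print(f"PC1/PC2 variance fractions: {qc['pca_variance_fractions'][0]:.2f} / "
      f"{qc['pca_variance_fractions'][1]:.2f}")
print(f"median chrX RniP: female {qc['rnip_median_female']:.4f} vs male "
      f"{qc['rnip_median_male']:.4f} (Mann-Whitney p = {qc['rnip_mannwhitney_p']:.2e})")
print(f"imputed PBMC labels for {qc['n_imputed_pbmc']} samples; "
      f"{len(qc['correlation_outliers'])} correlation outliers flagged cohort-wide")
vs = pd.read_csv(out / "varpart_summary.tsv", sep="\t", index_col=0)
print("median variance fraction by covariate:")
print(vs["median_fraction"].sort_values(ascending=False).round(3).to_string())
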