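"""Covariate-adjusted differential accessibility for the cohort contrasts.

NB-GLM Wald tests with FRiP, sequencer, sex, PBMC type, and case status as
covariates; BH adjustment across regions; DAR calls at adj-p < 0.01 with
|log2FC| > 0.5 (> 1 for the sex contrast).  The C9 contrast compares
repeat-expansion-positive ALS cases to verified-negative ones.
"""

import json
from pathlib import Path

import pandas as pd

from config import analysis_config
from imnatac.pipeline import stage_diff

config = analysis_config()
stage_diff(config)

out = Path(config.outdir)
dars = json.loads((out / "diff_summary.json").read_text())
for contrast, n in dars.items():
    print(f"{contrast}: {n} DARs")
c9 = pd.read_csv(out / "diff_c9_status.tsv", sep="\t")
top = c9.dropna(subset=["adj_p"]).nsmallest(1, "adj_p").iloc[0]
print(f"top C9 region {top.region_id}: log2FC = {top.log2fc:.2f}, adj p = {top.adj_p:.2e}")
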