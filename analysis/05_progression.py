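"""ALSFRS-R slope prediction from TSS-proximal accessibility.

Staged sample filters (correlation, slope IQR, batch size), a fixed 90/10
train/test split, then LASSO stability selection over fold-reassignment
reruns with per-run OLS refit and train-mean-anchored test R^2.
"""

import json
from pathlib import Path

import pandas as pd

from config import analysis_config
from imnatac.pipeline import stage_progression

config = analysis_config()
stage_progression(config)

out = Path(config.outdir)
flt = pd.read_csv(out / "progression_filter.tsv", sep="\t")
counts = flt["status"].value_counts()
print("filter chain:", counts.to_dict())
model = json.loads((out / "progression_model.json").read_text())
agg = model["aggregate"]
print(f"runs with a non-empty selection: {agg['n_nonempty_runs']:.0f} / {agg['n_runs']:.0f}")
if agg.get("support_size_mean") is not None:
    print(f"support size {agg['support_size_mean']:.1f} +/- {agg['support_size_se']:.1f} (mean +/- s.e.)")
    print(f"train RMSE/R^2: {agg['train_rmse_mean']:.3f} / {agg['train_r2_mean']:.3f}")
    print(f"test  RMSE/R^2: {agg['test_rmse_mean']:.3f} / {agg['test_r2_mean']:.3f}")
print(f"majority-vote set: {len(model['majority_set'])} regions")
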