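"""Shared configuration for the numbered analysis drivers.

All scripts write to results/analysis and derive their randomness from one
master seed, so the whole narrative is reproducible end to end.  The
stability-selection rerun count is held at 100 (a scaled-down rerun budget
that keeps the full narrative runnable on a laptop; the selection-frequency
machinery is identical at any count).
"""

from imnatac.pipeline import PipelineConfig

MASTER_SEED = 0


def analysis_config() -> PipelineConfig:
    return PipelineConfig(
        outdir="results/analysis",
        master_seed=MASTER_SEED,
        cohort_scale="desk",
        progression_n_runs=100,
    )
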