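# imnatac

Covariate-aware analysis of bulk ATAC-seq cohorts from iPSC-derived motor
neurons — for computational biologists who need the full chain from
per-sample peak calls to cohort-level findings, with every stage testable
against planted ground truth.

Large ALS cohort studies profile chromatin accessibility in motor-neuron
cultures derived from hundreds of patients and controls. In such data the
dominant variance is not disease: sex, the PBMC type the iPSC line came from
(epigenetic memory), ancestry, sequencer, and per-sample signal-to-noise
(FRiP) all drive strong signals, and naive case/control contrasts produce
false positives. This package implements the analysis chain that deals with
that reality:

* **Consensus peaks** — union-merge of per-sample peak calls, retaining
  intervals open in ≥ 10% of samples (variable width).
* **Normalization** — median-of-ratios size factors; per-region
  negative-binomial dispersions `Var = μ + αμ²` with a parametric trend
  `α(μ) = a₁/μ + α₀`; a calibrated variance-stabilizing transform (VST).
* **Differential accessibility** — per-region NB GLM with log link and
  size-factor offset, covariates (FRiP, sequencer, sex, PBMC type, case
  status), two-sided Wald tests, Benjamini–Hochberg adjustment, and DAR
  calls at adj-p and |log2FC| thresholds.
* **Variance partitioning** — per-region REML linear mixed model (random
  intercepts for categorical covariates, fixed effects for continuous ones),
  reporting variance fractions that sum to one.
* **X-inactivation statistics** — normalized chrX reads-not-in-peaks
  (RniP), the background-read dosage signature of the silenced X.
* **Progression predictor** — staged sample filters (correlation cluster,
  slope IQR, batch size), a 90/10 split, LASSO with 10-fold CV rerun under
  fold reassignment (stability selection), majority-vote region set, OLS
  refit, and train-mean-anchored test R².
* **Cis peak–gene mapping** — accessibility–expression association within
  250 kb of each TSS under covariate residualization
  (Frisch–Waugh–Lovell), Bonferroni correction, and classification of
  inverse and dual-sign pairs.

Because the real cohorts are gated behind data-use agreements, the package
ships a first-class **synthetic cohort generator** that plants all of the
above effects with recorded ground truth; every analysis is validated as a
recovery problem. See `docs/methods.md` for models, conventions, and the
generator's scope.

## Worked example

Run the numbered analysis drivers (they share `results/analysis/` and one
master seed), or the equivalent CLI stages:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_consensus_and_normalize.py
python analysis/04_differential.py
# ... or: imnatac all --outdir results/analysis --master-seed 0
```

Output of the drivers on the default desk-scale cohort (master seed 0):

```
cohort: 220 samples (190 ALS / 30 HC), 180 with a recorded ALSFRS-R slope
planted progression signal explains R^2 = 0.962 of slope variance over 25 promoter driver regions
consensus peak set: 5000 variable-width regions at the 10% occupancy threshold
dispersion trend alpha(mu) = 16.30/mu + 0.0274
median chrX RniP: female 0.0401 vs male 0.0203 (Mann-Whitney p = 6.27e-37)
imputed PBMC labels for 11 samples; 12 correlation outliers flagged cohort-wide
sex: 52 DARs
pbmc_type: 167 DARs
ancestry: 39 DARs
case_status: 2 DARs
c9_status: 3 DARs
top C9 region r04705: log2FC = -0.61, adj p = 0.00e+00
filter chain: {'retained_train': 137, 'retained_test': 16, 'excluded_correlation': 12,
               'excluded_slope_iqr': 9, 'excluded_batch': 6}
tested 57552 cis pairs over 176 matched samples
significant pairs at Bonferroni-adjusted p < 0.01: 272 (72 genes x 250 regions)
inverse-association fraction among significant pairs: 0.41
dual-sign peaks (positive to one gene, negative to another): 13
```

Reading this: the consensus stage recovers exactly the 5,000 true regions
(decoy peaks present in ~3% of samples fall below the 10% occupancy
threshold); the cohort-level dispersion trend sits above the generating
values (3/μ + 0.05) because marginal estimation absorbs the planted
covariate effects as apparent overdispersion — on effect-free data the
trend is recovered within a few percent (see the acceptance checks);
females carry roughly twice the male chrX background-read rate
(X-inactivation); the QC cut flags exactly the 12 planted decorrelated
samples, which are excluded before differential testing; the differential
stage finds the planted sex, PBMC-memory, and ancestry regions, almost no
case-status DARs at adj-p < 0.01 (the planted case effect is deliberately
weak, as in real cohorts), and recovers the C9-like promoter block at its
planted log2FC of -0.6; the predictor's staged filters remove the planted
correlation/slope/batch pathologies before the train/test split; and the
cis map recovers the planted peak-gene links, with the planted share of
inverse associations and dual-sign peaks.

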