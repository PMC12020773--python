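# chronodiet

Meal-timing pattern (MTP) analysis for repeated 24-hr dietary recalls, with
measurement-error correction and multiple-imputation misclassification
correction — plus a synthetic cohort generator so the whole pipeline is
testable end-to-end against known ground truth.

## What it does

1. **`synthetic_cohort`** — generates participants carrying one of three
   latent meal-timing archetypes ("early-often", "late-long",
   "late-infrequent-short"), meal-level recall records whose derived daily
   exposures equal the participant's true usual exposures plus day-to-day
   noise, and outcome z-scores with family (sibling) random effects.
2. **`recall_processing`** — turns meal-level records into five daily
   exposures (morning energy %, evening energy %, eating window, pre-sleep
   fasting, eating frequency) plus energy aggregates; applies the <500 kcal
   day exclusion; computes habitual sleep (5/7 weekday + 2/7 weekend
   weighting); flags misreported days via Goldberg cutoffs on EI/BMR with
   Schofield BMR equations.
3. **`usual_exposure_model`** — Stage 1: per-exposure Box-Cox-transformed
   linear mixed models with a person random intercept (sex, weekend, age,
   education, BMI z covariates). Supports regression-calibration prediction
   (shrunken BLUP, bias-corrected back-transform) and outcome-conditioned
   posterior draws for the imputation loop. Energy proportions are derived
   as ratios of usual window energy to usual total energy.
4. **`mtp_clustering`** — Stage 2: z-score standardisation, k-means (k=3
   default, best of 25 starts), signature-based pattern naming, and a frozen
   deterministic classification function.
5. **`mi_association`** — Stage 3 + MI loop: linear mixed models of outcome
   z-scores on MTP membership vs "early-often" with a family random
   intercept; M repetitions of draw → classify → fit; Rubin's-rule pooling
   with 95% CIs. Covariate sets: basic / puberty / energy+HFI / fully
   adjusted; optional plausible-reporters-only sensitivity analysis.
6. **`exposure_selection`** — exhaustive best-subset selection over the five
   usual exposures (BIC on ML fits, covariates fixed) with family-level
   bootstrap percentile CIs.
7. **`pipeline_cli`** — `chronodiet` CLI orchestrating everything with one
   global seed, config snapshots, and per-stage filter accounting.

Table formats are documented in [SCHEMA.md](SCHEMA.md).

## CLI

```bash
chronodiet run-all --out-dir run --seed 1 --m 500 --b 1000
# or stage by stage:
chronodiet simulate --out-dir data --seed 1 --n 2000
chronodiet derive --recalls data/recalls.tsv --participants data/participants.tsv --out daily.tsv
chronodiet usual --exposures daily.tsv --covariates data/participants.tsv --mode rc --out usual.tsv
chronodiet cluster --usual usual.tsv --k 3 --out mtp_model.json
chronodiet associate --exposures daily.tsv --covariates data/participants.tsv \
    --outcomes data/outcomes.tsv --m 500 --model basic --seed 1 --out assoc.tsv
chronodiet select --usual usual.tsv --covariates data/participants.tsv \
    --outcomes data/outcomes.tsv --b 1000 --seed 1 --out select.tsv
```

Exit codes: 0 ok, 1 validation error, 2 stage failure.

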