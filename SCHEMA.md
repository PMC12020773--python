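# Table schemas

All tables are tab-separated text with a header row. Clock times are minutes
since midnight of the recall day (values ≥ 1440 are post-midnight intake);
durations are hours; energies are kcal.

## participants.tsv (covariate table)

| column | description |
|---|---|
| participant_id | unique id |
| family_id | shared by siblings |
| latent_archetype | simulation-only ground-truth pattern label; ignored by the analysis stages |
| age | years |
| sex | `M` / `F` |
| country | one of ITA, EST, CYP, BEL, SWE, GER, HUN, ESP |
| isced | parental education, `low` / `high` |
| bmi_z | BMI z-score |
| puberty | 0/1 |
| weight_kg | body weight (Schofield BMR input) |
| sleep_noct_wd, sleep_nap_wd | weekday nocturnal / nap sleep, hours |
| sleep_noct_we, sleep_nap_we | weekend nocturnal / nap sleep, hours |

## recalls.tsv (meal level, one row per eating occasion)

| column | description |
|---|---|
| participant_id | id |
| day_index | 0-based recall day within participant |
| weekend | 0/1 |
| occasion_time_min | clock time of the occasion |
| energy_kcal | occasion energy |
| healthy | 0/1 healthy-food flag |
| wake_min, bed_min | wake and bed time of that day |

## daily_exposures.tsv (one row per recall day)

| column | description |
|---|---|
| participant_id, day_index, weekend | keys |
| total_kcal, healthy_kcal, unhealthy_kcal | energy aggregates |
| morning_kcal, evening_kcal | energy inside [05:00, 11:00) / [17:00, 24:00) |
| morning_pct, evening_pct | window energy as % of total |
| eating_window_h | last minus first occasion |
| presleep_fasting_h | bed time minus last occasion (may be negative; NaN if bed time missing) |
| eating_frequency | occasion count (after optional merge gap) |
| plausibility | `plausible` / `misreporter` / `excluded_low_energy` |

## outcomes.tsv

`participant_id`, plus outcome z-scores: `homa_ir_z`, `hba1c_z`,
`triglycerides_z`.

## usual_rc.tsv / MI draw tables

`participant_id`, the five usual exposures (`morning_pct`, `evening_pct`,
`eating_window_h`, `presleep_fasting_h`, `eating_frequency`), usual
`total_kcal` and `healthy_kcal`, `provenance`
(`regression_calibration` / `mi_draw`), and `draw_index` for MI draws.

## mtp_model.json

Frozen Stage-2 artifact: standardisation `means`/`sds`, `centroids` (k×5,
standardised space), `names`, `k`, `n_starts`, `seed`, `inertia`,
`exposure_names`.

## association_results.tsv

One row per MTP contrast: `outcome`, `model`, `contrast`, `beta`, `ci_low`,
`ci_high`, `within_var`, `between_var`, `total_var`, `df`, `m`.

## selection_results.tsv

One row per selected exposure: `exposure`, `beta`, `ci_low`, `ci_high`,
`criterion`, `criterion_value`, `n_bootstrap`.
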