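# Data dictionary

All tabular I/O is comma-separated text with a header row.

## Feature table (`cohort.csv`)

| column          | type    | units / levels                                   |
|-----------------|---------|--------------------------------------------------|
| participant_id  | string  | unique                                           |
| cohort          | string  | `train`, `validation`, `test`                    |
| diagnosis       | string  | `CN`, `sMCI`, `pMCI`, `AD`                       |
| subclass        | string  | simulator ground truth: `negative`, `low_confidence`, `high_confidence` (optional) |
| age             | float   | years                                            |
| sex             | float   | 0 / 1 (1 = female)                               |
| mean_gmv        | float   | mean modulated grey-matter density               |
| tiv             | float   | total intracranial volume, cm³                   |
| adas13          | float   | ADAS-Cog 13-item total, higher = worse           |
| mem             | float   | composite memory score (z-scale)                 |
| exec            | float   | composite executive score (z-scale)              |
| bnt             | float   | Boston Naming Test total                         |
| clock           | float   | clock-drawing score                              |
| vbm_1 … vbm_k   | float   | subtype weights, spatial correlations in [−1, 1] |
| abeta           | float   | CSF amyloid-beta 1-42, pg/mL (optional)          |
| tau             | float   | CSF total tau, pg/mL (optional)                  |
| apoe4           | float   | APOE ε4 carrier flag 0 / 1 (optional)            |

## Risk classes (`classes.csv`)

participant_id, diagnosis, stage1_hit (bool), stage1_score (SVM decision
value, positive = dementia side), stage2_probability, risk_class
(`negative` / `low_confidence` / `high_confidence`).

## Metrics (`metrics.csv`)

model, sensitivity, specificity, ppv, accuracy, adjusted_ppv, prevalence —
proportions in [0, 1]; empty cells mean the defining denominator was zero.

## Tuning audit (`tuning.csv`)

n_subsamples, fraction, sensitivity, specificity, ppv, accuracy, tp, fp,
tn, fn, constraint_met (sensitivity ≥ 0.30), selected.

## Enrichment (`enrichment.csv`)

trait, observed_proportion (in the high-confidence subgroup), group_size,
reps, p_value (one-sided, uncorrected), dropped_missing.

## Visit table (trajectories)

participant_id, group, visit_month, adas13 — one row per participant-visit.

## Voxel maps (CSV dialect)

Participants × voxels matrix with the participant id as the index column;
an optional `true_subtype` column carries simulator ground truth. NIfTI
import/export is available when spatial metadata (grid shape, affine,
binary mask) is supplied.
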