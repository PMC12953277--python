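# fractalct

3D box-counting fractal dimension (FD) of segmented tumor volumes on CT,
with the downstream risk-modelling and prognosis analyses that turn the FD
into a biomarker: univariable screening, multivariable logistic models
(clinical / FD / combined), DeLong AUC comparison, Youden cut-off selection,
Hosmer–Lemeshow calibration, decision-curve analysis, ICC reliability, and
Kaplan–Meier / log-rank risk stratification.  Because no patient data ship
with the package, a first-class synthetic module provides analytic fractal
phantoms, rough-tumor masks, and cohort simulators calibrated to published
summary statistics.

## Layout

| Module | Contents |
| --- | --- |
| `fractalct.preprocess` | NIfTI / DICOM ingestion, isotropic resampling (linear for images, nearest-neighbour for masks), 256-level intensity quantization, ROI cropping, largest-component selection |
| `fractalct.fractal` | box-size schedules, occupied-box counting (bounding-box anchored), log–log OLS dimension fitting, sliding-window local FD maps, end-to-end per-patient FD records |
| `fractalct.synthetic` | phantoms (cube / slab / line / sphere / Menger sponge), seeded rough-tumor masks, label-conditional + joint-logistic + voxel-level cohort simulators |
| `fractalct.stats_models` | IRLS logistic regression with Wald inference, p < α screening, VIF, risk scoring, Youden cut-off |
| `fractalct.evaluation` | DeLong AUC/CI and paired test, sensitivity/specificity/accuracy, Hosmer–Lemeshow, decision curves, ICC(2,1), Kaplan–Meier, log-rank |
| `fractalct.pipeline` | YAML-configured `run_study` orchestration with deterministic report bundles |

## CLI

```bash
fractalct simulate --mode table --n 406 --seed 1 --out cohort.csv
fractalct fd --volume vol.nii --mask mask.nii --out fd.csv --schedule pow2
fractalct fit-model --cohort cohort.csv --model combined --out model.json --scores scores.csv
fractalct evaluate --scores scores_labeled.csv --out metrics.json
fractalct survival --cohort cohort.csv --out survival.json
fractalct reliability --ratings ratings.csv --out icc.json
fractalct run-study --config study.yaml --seed 1 --out study_out/
```

`run-study` executes the whole replica (simulate → FD → screen → models →
ROC/DeLong/HL/DCA → Youden stratification → KM/log-rank) and writes
`metrics.json`, per-stage CSV tables, a config echo and a run log; two runs
with the same seed and config are byte-identical.

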