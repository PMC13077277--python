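# gaitpipe

Smartphone gait-video analytics from 2D pose-landmark time series: gait-cycle
segmentation, geometric feature extraction, and leakage-guarded evaluation of
sex and age-group classifiers.

## The problem

Gait assessment is a gold-standard geriatric screen, but lab-grade motion
capture is out of reach for most low-resource clinics. A far cheaper
alternative: record a person walking 5–6 m with a phone camera placed
perpendicular to the walking path, run a markerless pose estimator (e.g.
MediaPipe in 2D mode, which emits 33 named landmarks per frame at 30 Hz),
and ask whether simple classifiers can recover biologically meaningful
attributes — sex, and age group (< 65 vs ≥ 65 years) — from the extracted
gait geometry. If they can, the protocol carries enough signal to justify
pursuing clinical phenotypes next.

`gaitpipe` is that analytic chain, built for people working with
pose-landmark exports rather than raw video:

1. **Cycle segmentation** — the distance between the two ankles dips to a
   prominent local minimum twice per stride; a gait cycle spans three
   consecutive minima, cycles tile without overlap, and only the *second*
   cycle is analyzed (clear of the recording edge). Recordings where no
   plausible cycle exists (e.g. the estimator latched onto scene content)
   are reported as typed failures, feeding a feasibility rate.
2. **Feature extraction** — per frame of the second cycle, 15 joint-pair
   distances (converted to meters via an in-video reference object) and 12
   interior joint angles; each series summarized by mean, SD, skewness and
   kurtosis, plus the cycle's frame count as a walking-speed surrogate:
   15·4 + 12·4 + 1 = **109 features**.
3. **Evaluation** — repeated stratified 5-fold cross-validation (20
   repetitions → 100 evaluations per condition) with strict leakage
   guarding: z-scaling, elastic-net |coefficient| feature ranking, top-k
   selection (k = 1..50) and classifier fitting all happen inside the
   training fold. Two models (elastic-net logistic regression,
   histogram gradient boosting), metrics AUC-ROC / accuracy / per-class
   sensitivity and F1 / MCC, aggregated into performance-vs-k curves.
4. **Sensitivity analyses** — BMI-stratified metrics, per-site re-runs,
   best/worst-predicted individuals, feature-selection frequencies and
   per-class feature distributions.
5. **Synthetic cohorts** — a seeded sagittal-plane kinematic walker with
   tunable sex/age effects, landmark jitter and unflagged detection
   failures, so the whole chain runs and is tested without any video data.

## Worked example

The numbered scripts under `analysis/` run the full study emulation and
write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_segment_and_extract.py
python analysis/03_evaluate_classifiers.py
python analysis/04_sensitivity_analyses.py
python analysis/05_calibration_checks.py
```

`02` prints the feasibility of cycle extraction on a 155-recording cohort
that includes a 6.5% rate of unflagged pose-detection failures:

```
extracted 147/155 recordings (94.8%)
feature table: 147 rows x 109 feature columns -> results/features.csv
failures by reason:
irregular_cadence    8
```

All 8 failures are the simulated detection failures, caught by the
cadence-regularity gate. `03` then reports discrimination at 15 selected
features:

```
sex: AUC at k=15 enet_lr=0.869 (SD 0.054), hist_gb=0.884 (SD 0.060)
age: AUC at k=15 enet_lr=0.697 (SD 0.092), hist_gb=0.675 (SD 0.081)
```

Sex is recovered well (AUC near 0.9, driven by shoulder/hip geometry — `04`
shows `d_left_shoulder__right_shoulder_mean` as the most-selected feature),
age only moderately (AUC near 0.7, led by the speed surrogate
`cycle_n_frames`), and sex beats age at every k in the sweep — the
qualitative ordering the analysis is designed to detect. Each AUC's SD is
across the 100 resampled evaluations (5 folds × 20 repetitions).

The same chain is available as a CLI for one-off use
(`gaitpipe simulate|segment|extract|evaluate|sensitivity|run|report`), and as a single
orchestrated run with a manifest of content-hashed outputs:

```python
from gaitpipe import demo_config, run_pipeline
run_pipeline(demo_config(), "out/")   # byte-identical on rerun
```

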