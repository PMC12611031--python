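# ecgms

Screening for metabolic syndrome (MS) from multi-lead ECG recordings.

MS — the cluster of abdominal obesity, hypertension, dyslipidemia and
elevated fasting glucose — leaves measurable traces in the surface ECG:
altered beat-to-beat variability, QRS morphology and frontal-plane cardiac
axis. `ecgms` implements a complete, testable pipeline that turns raw
multi-lead ECG into a subject-level MS/control decision, for researchers in
physiological signal processing who want every stage reproducible and
validated against ground truth:

1. **Synthetic cohort generator** — template-based multi-lead ECG with exact
   beat-level Q/R/S ground truth, programmable group contrasts (axis shift,
   RR variability, QRS width, R amplitude) and SNR-exact noise. It stands in
   for the unavailable clinical OGTT cohort (15 MS + 10 control, five
   stages, 1 kHz) and makes every downstream stage checkable to the sample.
2. **Delineation** — Pan–Tompkins R detection (band-pass → derivative →
   squaring → integration → adaptive thresholds), then S as the first
   derivative-inversion minimum after R, and Q by running the same S search
   on the time-reversed signal `x̃[n] = x[N−1−n]` and mirroring the index
   back.
3. **Features** — the 30-entry vector: per lead (I, aVF) mean/variance of
   RR, RS, QS, QR intervals, R/Q and R/S amplitude ratios and R amplitude,
   plus mean/variance of the per-beat cardiac axis
   `θ = atan2(net_aVF, net_I)`.
4. **Classifiers** — RBF-SVM and RobustBoost (100 tree cycles,
   boost-by-majority potential scheme) on the feature vectors; a 10-layer
   CNN (conv 100@5×5 → ReLU → pool → conv 100@8×8 → ReLU → pool → FC →
   softmax, SGD with momentum, lr 1e-4 dropped ×0.1 per 8 epochs, L2 4e-4,
   5 epochs, batch 30) on raw 300-window signal segments.
5. **Evaluation & statistics** — subject-wise stratified 10-fold CV with
   the standard confusion-matrix metrics (FPR, FNR, PPV, NPV, Se, Sp, Acc),
   a repeated-CV accuracy histogram (500 runs), KS normality screen,
   Mann–Whitney and point-biserial Pearson tests per feature and stage, PCA
   relevance filtering (|loading| ≥ 0.2), and Bland–Altman agreement for
   detector validation.

See `docs/methods.md` for the models, assumptions and design decisions.

## Worked example

```python
from ecgms import CohortSpec, RunConfig, run_pipeline
import json

cfg = RunConfig(
    cohort=CohortSpec(duration=30.0, sample_rate=500.0, stages=("basal",), seed=7),
    method="svm", k=10, seed=7, out_dir="demo_run",
)
manifest = run_pipeline(cfg)
print(json.dumps(manifest["summary"], indent=2))
```

prints

```json
{
  "r_peak_mean_difference_ms": 0.0,
  "cv_mean_accuracy": 1.0,
  "pca_retained_features": 30,
  "mw_significant_fraction": 0.43333333333333335
}
```

Reading the numbers: the detector's R marks agree with the generator's
ground truth with zero mean Bland–Altman difference; the SVM separates the
MS and control groups perfectly under subject-wise 10-fold CV (the default
synthetic group contrasts are deliberately strong); all 30 features carry
PCA loadings ≥ 0.2 on some retained component; and 43% of the 30
feature-stage tests reject equality of the two groups at 0.05 — the
programmed effects move interval, axis and amplitude features but not every
ratio feature. `demo_run/` then contains `features.csv`, `cv_report.csv`,
`feature_screen.csv` and a `manifest.json` tying every artifact to the
seed.

The same stages are scriptable from the shell:

```sh
ecgms simulate --config cohort.yaml --out records/ --seed 1
ecgms detect --record records/ms01_basal.csv --out ann.csv
ecgms features --records records/ --out features.csv
ecgms evaluate --features features.csv --method svm --k 10 --reps 500 --seed 1 --out report/
ecgms stats --features features.csv --out stats/
ecgms agree --ref records/ms01_basal_truth_ann.csv --test ann.csv --out ba.csv
ecgms run --config run.yaml --seed 1 --out run_out/
```

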