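# defaceqc

Quality control for brain-MRI defacing.

Sharing head MRI data requires *defacing* — removing the nose, eyes, mouth
and surrounding soft tissue so a 3D render of the scan can no longer be
matched to a photograph. Defacing tools fail in characteristic ways: they
leave residual facial features, perturb voxel intensities across nearly the
whole volume, or clip into brain tissue. Checking thousands of defaced scans
by eye does not scale. `defaceqc` automates that review: it compares each
defaced scan with its original, condenses the comparison into a small set of
interpretable image features, and classifies the pair as *successfully* (0)
or *insufficiently* (1) defaced.

It is written for data managers and researchers running anonymization
pipelines on neuroimaging archives, and for methodologists studying defacing
QA itself.

## What it computes

For an original volume $I_o$ and its defaced counterpart $I_d$ (same grid,
min–max normalized per volume, head mask $M_h = \{x : I_o(x) > 0.03\}$,
brain mask $M_b$ supplied):

**Volumetric measures**

- impacted voxels: $100 \cdot |\{x \in M_h : |I_o(x) - I_d(x)| > \varepsilon\}| / |M_h|$
- removed voxels ("head loss"): $100 \cdot |\{x \in M_h : I_o(x) \ne 0 \wedge I_d(x) = 0\}| / |M_h|$
- the same two restricted to the brain mask ("brain loss")
- brain-to-head ratio $|M_b| / |M_h|$ (a brain-mask sanity indicator)

**Similarity metrics** — both volumes are rendered from five standardized
perspectives (frontal, left/right profile, left/right 45°) by orthographic
first-hit ray casting, and each pair of corresponding views is scored with
RMSE, PSNR, SSIM and FSIM, averaged over the five views. FSIM combines
phase congruency (log-Gabor filter bank) with gradient magnitude and is the
most face-sensitive of the four.

**Classification** — the per-pair feature vector (4 similarity metrics,
3 volumetric measures, 4 one-hot defacing-method indicators) feeds four
classifiers (logistic regression, MLP, random forest, XGBoost) evaluated
under *nested stratified group k-fold cross-validation*: the outer loop
(default k=5) estimates generalization, the inner loop (default k=3) tunes
hyperparameters on training folds only, all scans of one subject stay in a
single fold, and class proportions are preserved per fold as far as the
group constraint allows. Permutation feature importance plus hierarchical
clustering of Spearman rank correlations drives an iterative feature-
selection loop. Percent agreement and Cohen's κ quantify inter-rater
reliability of manual labels.

Because clinical registries cannot be redistributed, the package ships a
synthetic head-phantom generator (ellipsoidal head + brain with
parameterized nose/eye/mouth protrusions) and a defacing simulator covering
the observed failure modes, with strict/lenient ground-truth label rules.
All testing and the acceptance script run on this substrate.

## Worked example

```python
import defaceqc as dq
from defaceqc.features import phantom_feature_table, modeling_table
from defaceqc.cv import CVConfig

manifest = dq.generate_cohort(
    n_subjects=12, scans_per_subject=(1, 2), positive_fraction=0.5,
    master_seed=7, grid_size=48,
)
features = phantom_feature_table(manifest, resolution=64)
table = modeling_table(features, criterion="lenient")
qa = dq.DefacingQA(table, CVConfig(outer_folds=3, inner_folds=2,
                                   models=("LR", "RF"), seed=7))
res = qa.fit()
print(res.summary())
```

prints per-classifier outer-fold means with standard deviations:

```
          accuracy  sensitivity  specificity    precision        auroc
model
LR     0.90 (0.10)  0.82 (0.24)  0.97 (0.04)  0.97 (0.05)  0.97 (0.03)
RF     0.94 (0.05)  0.94 (0.10)  0.95 (0.09)  0.95 (0.09)  1.00 (0.00)
```

Sensitivity is the detection rate of *insufficiently defaced* scans — the
privacy-relevant event. `res.importances["RF"]` ranks the features by mean
AUROC drop under permutation, and `res.final_bundle()` refits the best model
on all data for deployment (`bundle.predict(rows)` returns labels and
scores). The synthetic cohort is deliberately easier to separate than
clinical data, so these numbers characterize the pipeline, not real-world
performance.

The same pipeline is available from the shell:

```sh
defaceqc simulate --n-subjects 12 --grid-size 48 --seed 7 --out-dir cohort/
defaceqc features --orig-dir cohort/ --defaced-dir cohort/ --out features.csv
defaceqc train --features labeled.csv --criterion lenient --out-dir run/
defaceqc predict --bundle run/model_bundle.joblib --features rows.csv --out pred.csv
defaceqc agreement --labels raters.csv --out agreement.csv
```

Defaced files pair with originals by the `<scan_id>_<method>.nii.gz` suffix
convention; subject identity and labels are joined from the cohort manifest.

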