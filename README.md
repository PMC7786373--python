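# lesionview

Classify 3D brain-lesion volumes — neuromyelitis optica spectrum disorder
(NMOSD) versus multiple sclerosis (MS) — from automated white-matter-
hyperintensity (WMH) segmentations, using **two-view compressed 2D residual
networks**, with conventional 3D residual baselines for comparison.

Both diseases produce scattered, spatially overlapping T2-FLAIR
hyperintensities, and clinical cohorts are small (tens of subjects), which
leaves 3D convolutional networks badly over-parameterised.  The package's
core operator is a *compression block* that folds one spatial axis of a
cube volume `x(h, w, l)` into the channel axis of a 2D image and compresses
it with a single strided convolution:

    x(h,w,l) → x1(c=h, w, l)          x(h,w,l) → x2(c=w, h, l)
    y_i = ReLU(BN(conv2d_{7×7, stride 3, 32ch}(x_i)))     i = 1, 2
    y   = concat(y1, y2)                                   (64 channels)

The fused 64-channel map enters a standard 18- or 34-layer residual
backbone at its first pooling stage (the 7×7 stem is omitted), so
2D-pretrained backbone weights transfer with no adapters and the model has
roughly a third of the parameters of its 3D counterpart
(11,475,330 vs 33,161,986 at depth 18).

The package is aimed at neuroimaging ML researchers who want the full
pipeline — NIfTI I/O, crop/resize/normalise preprocessing, paired
shift/flip augmentation, synthetic two-class lesion phantoms, subject-level
repeated 5-fold cross-validation — runnable end-to-end on a CPU without any
deep-learning framework: the networks run on a compact numpy engine with
explicit, finite-difference-verified backward passes (`lesionview.nn`).

## Worked example

```python
import numpy as np
from lesionview import (PhantomParams, generate_cohort, cohort_summary,
                        ModelSpec, CompressionConfig, build_model,
                        count_learnable_parameters,
                        TrainConfig, make_fold_plan, run_repeated_cv)

# parameter accounting of the reference models
for family, depth in [("two_view_2d", 18), ("resnet3d", 18)]:
    n = count_learnable_parameters(build_model(ModelSpec(family, depth)))
    print(family, depth, n)

# a small, strongly separated synthetic cohort (32-voxel cubes)
params = PhantomParams.easy(side=32, seed=7)
cohort, _ = generate_cohort(params, n_ms=16, n_nmosd=16, seed=7)
print(cohort_summary(cohort)[["n", "lesion_fraction_mean"]])

# repeated cross-validation of the depth-18 two-view model on lesion masks
spec = ModelSpec("two_view_2d", 18,
                 compression=CompressionConfig(per_view_in_channels=30))
plan = make_fold_plan([s.subject_id for s in cohort], k=4, repeats=2,
                      master_seed=7)
report = run_repeated_cv(cohort, spec, TrainConfig(epochs=25, seed=7), plan)
for m in ("accuracy", "sensitivity", "specificity"):
    a = report.aggregate[m]
    print(f"{m}: {a['mean']:.3f} ± {a['sd']:.3f}")
```

prints (a couple of minutes on one CPU)

```
two_view_2d 18 11475330
resnet3d 18 33161986
        n  lesion_fraction_mean
label
MS     16              0.019463
NMOSD  16              0.001865
accuracy: 0.859 ± 0.047
sensitivity: 1.000 ± 0.000
specificity: 0.719 ± 0.094
```

The two parameter totals are the exact learnable-parameter counts of the
two reference architectures.  The cohort summary shows the intended 10×
lesion-burden gap between the classes (≈2% vs ≈0.2% of brain volume); on
these strongly separated phantoms the depth-18 two-view model reaches 0.86
cross-validated accuracy from 24 training subjects per fold (sensitivity
is for NMOSD, the positive class).  Larger cohorts push this above 0.98
(see `tests/test_acceptance.py`), while with the default — clinically
calibrated, overlapping — phantom parameters the task is deliberately hard
and accuracy drops toward chance: separating realistic overlapping cohorts
is exactly the hard problem the architecture was designed for.

The same operations are exposed as a CLI:

```sh
lesionview simulate --out cohort/ --n-ms 47 --n-nmosd 41 --seed 1 --easy
lesionview preprocess --manifest cohort/manifest.csv --out proc/ --side 100
lesionview count-params --family two_view_2d --depth 34
lesionview cv --manifest proc/manifest.csv --depth 18 --repeats 15 \
              --folds 5 --epochs 20 --seed 1 --out report.json
```

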