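# mitomorph

Machine-learning classification and quantification of mitochondrial
morphology in fluorescence micrographs (2D) and confocal / serial block-face
scanning electron microscopy stacks (3D).

Mitochondria continually undergo fission and fusion, and the balance between
the two shifts under stress: networks fragment, tubules swell and round up,
punctate fragments accumulate. `mitomorph` implements an image-cytometry
pipeline that turns micrographs into per-image morphology profiles:

1. **Preprocess** — rolling-ball background subtraction (10 px), unsharp
   masking (radius 1 px, weight 0.60), CLAHE (256 bins) and a disc median
   filter (radius 2 px), in that fixed order.
2. **Segment** — a trainable random-forest pixel classifier over a
   Gaussian-family feature stack (or Otsu thresholding), a 0.30 µm² minimum
   particle size in 2D, per-slice morphological erosion and connectivity-6
   component labeling in 3D, and 5× bilinear compression of EM images before
   segmentation.
3. **Measure** — 32 size/shape descriptors per 2D object (area, Crofton
   perimeter, convex hull, moment ellipse, Feret calipers, skeleton
   topology, thickness, …) or 8 descriptors per 3D object (volume, mesh
   surface area, sphericity, 3D Feret, ellipsoid elongation/flatness,
   extent).
4. **Classify** — a 500-tree random forest over the z-scored descriptors.
   Each object is assigned to one of four phenotypes — **network** (branched,
   ≳ 5 µm²), **unbranched** (1–4 µm² tubes), **swollen** (1–4 µm², round) and
   **punctate** (≲ 1 µm²) — by the majority of tree votes. Training uses a
   stratified 80/20 split with hyperparameters selected over 25 bootstrap
   repetitions.
5. **Quantify** — the endpoint per image is the percentage of total
   mitochondrial area (volume in 3D) in each morphology class, with
   mean ± SD aggregation across experimental groups.

A built-in synthetic-data generator renders widefield-like 2D images and
confocal/EM-like 3D volumes of all four classes with ground-truth labels, so
the entire pipeline runs and is tested without any external data.

## Worked example

```python
import mitomorph as mm

# 300 labeled synthetic objects per class, measured with 32 descriptors
table = mm.sample_object_table(mm.SynthSpec2D(n_per_class=300, seed=1))

train, test = mm.split_train_test(table, 0.8, seed=2)
model = mm.train_random_forest(train, n_trees=500, n_repetitions=25, seed=3)
cm, acc = mm.evaluate(model, test)
print(f"resample accuracy {100 * model.training_accuracy:.1f}%")
print(f"test accuracy     {100 * acc:.1f}%")
print(cm.to_frame())
```

prints

```
resample accuracy 100.0%
test accuracy     100.0%
            network  unbranched  swollen  punctate
network          60           0        0         0
unbranched        0          60        0         0
swollen           0           0       60         0
punctate          0           0        0        60
```

The resample accuracy is the mean out-of-bag accuracy over the 25 bootstrap
repetitions used for model selection; the test accuracy is the fraction of
the held-out 20% classified correctly, and the confusion matrix tallies true
(rows) versus predicted (columns) objects. On the cleanly generated
geometries the four classes are fully separable, so both accuracies sit at
100%; on real hand-classified data they are lower.

The same works end to end from the shell:

```sh
mitomorph run-2d --seed 0 --out results/run2d
mitomorph run-3d --seed 0 --out results/run3d
```

which writes preprocessed images, masks, descriptor tables, the trained
model, per-object predictions and per-image morphology profiles.

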