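# Methods

## The classification model

Each segmented mitochondrial object is described by a fixed geometric
feature vector and assigned one of four morphology phenotypes — network,
unbranched, swollen, punctate — by a random forest of 500 decision trees.
Prediction is by majority vote of the trees; vote ties are broken by the
fixed class order network < unbranched < swollen < punctate so that
prediction is deterministic.

Training follows a fixed protocol: the labeled object table is split into
training (80%) and test (20%) sets, stratified by class with ⌈0.8·n_c⌉ rows
per class going to training. The only tuned hyperparameter is the number of
features considered per split, drawn from {⌊√p⌋/2, ⌊√p⌋, 2⌊√p⌋}. For each
candidate, 25 bootstrap resamples of the training set are drawn (the same 25
resamples for every candidate, so candidates compete on identical sampling
noise); a 500-tree forest is fitted on each resample and scored on the rows
left out of that resample, and the candidate with the best mean accuracy
wins. The reported *training accuracy* is that winning mean resample
accuracy — an out-of-bag estimate, not a refit-on-self accuracy. The final
forest is refitted on the full training set with the winning candidate. An
alternative reading of "25 repetitions" — 25 independent refits of the final
model — would not provide out-of-bag accuracy estimates and was not used.

The z-scoring used by the PCA and class-mean heatmap analytics uses the
sample (n−1) standard deviation; constant columns map to zero. The PCA sign
convention makes the largest-magnitude loading of each axis positive.

## Descriptor suites

The 2D suite has exactly 32 measurements per object. The upstream tool
chain this package mirrors never enumerates its measurement list, so the
suite here is this package's own canonical reconstruction: it contains every
descriptor that the morphology definitions rely on (area, roundness,
circularity, interfacial density, skeleton branch points) plus the standard
extended geometric measures. Fixed conventions:

* lengths in µm, areas in µm²; pixel size always travels with the data;
* perimeter by the 4-direction Crofton estimator;
* convex hull taken over pixel *corner* points (pixels as unit squares), so
  convex area and convex perimeter are continuous polygon measures;
* ellipse fit from the pixel-centre covariance plus the 1/12 variance of a
  unit square (keeps 1-px-wide objects non-degenerate); axis length
  4·sqrt(eigenvalue); angles in degrees in [0, 180);
* Feret calipers from the convex hull (max pairwise distance; min width by
  edge-normal projection);
* skeleton = 2D topological skeleton; branch point = skeleton pixel with
  ≥ 3 skeleton neighbours (8-neighbourhood), end point = exactly 1; skeleton
  length sums 8-adjacency edges (1 / √2); thickness = 2 × Euclidean distance
  transform sampled on the skeleton;
* holes = enclosed 4-connected background components (holes are *not*
  filled during segmentation, so this descriptor stays informative);
* circularity, roundness, sphericity and convexity are capped at 1, since
  digitization can push the raw ratios slightly above the continuous bound.

The 3D suite has 8 measurements: volume, surface area of the marching-cubes
mesh at level 0.5 (voxel-size-aware), sphericity π^⅓(6V)^⅔/SA capped at 1,
equivalent sphere diameter, maximal 3D Feret (exact over hull vertices;
brute force for tiny objects), elongation √(λ₁/λ₂) and flatness √(λ₂/λ₃)
from the voxel-covariance eigenvalues with every eigenvalue floored at the
within-voxel variance (min voxel dimension)²/12 so rods and plates stay
finite, and bounding-box extent.

## Preprocessing chain

Order: rolling ball (radius 10 px) → unsharp mask (radius 1 px, weight
0.60) → CLAHE (256 bins) → disc median filter (radius 2 px). All stages
work in floating point with reflect borders; binarization happens only at
segmentation.

* The rolling ball is implemented exactly as grayscale opening with a
  non-flat ball structuring element (height √(r²−d²)), subtracted from the
  input — not the sliding-paraboloid approximation — so it is directly
  testable against a brute-force opening.
* The unsharp mask uses the (I − w·G_σ(I))/(1 − w) convention with σ equal
  to the radius, clipped below at zero only (clipping above would destroy
  the sharpening overshoot).
* Only the CLAHE bin count is externally fixed; block size (127 px) and
  maximum slope (3.0) follow the defaults of the plugin family the chain
  mirrors and are exposed in `PreprocessConfig`. The slope cap is mapped to
  a clip limit of `max_slope / bins` of the tile pixel count per bin. The
  output is rescaled to the input intensity range. Note that CLAHE's tile
  grid is anchored to the image frame, so unlike the other three stages it
  is not shift-equivariant; the equivariance tests therefore cover the
  three translation-invariant stages.
* Two-channel input (e.g. an inner- and an outer-membrane marker) is merged
  by pixel-wise maximum before preprocessing (`merge_channels`; `sum` is
  available), preserving whichever membrane signal is stronger.

## Segmentation

The trainable pixel classifier is a random forest over a per-pixel feature
stack: raw intensity, Gaussian smoothings, gradient magnitudes, Laplacians
at σ ∈ {1, 2, 4, 8}, and difference-of-Gaussians for adjacent σ pairs. It
is trained from sparse tri-state annotation masks (mito / background /
unlabeled). Otsu and fixed thresholding are available as fully automated
fallbacks, but on realistic images where objects cover well under 1% of the
pixels a global threshold fails (the histogram is dominated by background),
which is exactly why the pixel-classification route is the pipeline default.
In the built-in synthetic workflows the annotations are sampled from the
generator's ground truth, playing the role of hand scribbles.

2D particle analysis uses 8-connectivity and discards objects below
0.30 µm². The minimum size is interpreted as an area (the particle-analysis
convention); the alternative reading as a 0.30 µm length would correspond to
a ~0.07 µm² disc and would keep single-pixel noise. 3D labeling uses
connectivity 6 (faces only) by default. Erosion (one iteration of the
smallest standard element — a 3×3 cross in 2D — applied per slice before
stacking, matching the order of the workflow it reproduces) counteracts the
segmentation "ballooning" of bright objects; the element and iteration
count are configurable since the upstream description fixes neither. EM
images are inverted (they are bright-background) and compressed 5× by
bilinear interpolation before segmentation; the morphology classifier for
the EM workflow is trained at the post-compression voxel size, because that
is the scale at which segmented objects are measured.

## Synthetic data generator

The generator emulates the study conditions rather than any particular
dataset: widefield-like 2D micrographs at 0.1 µm/pixel and confocal-like
(50 × 0.1 µm slices) or SBF-SEM-like (100 × 0.07 µm slices, inverted
contrast) stacks. Object geometry follows the class definitions:

* **network** — a random tree of 3–5 tube segments (width 0.35–0.5 µm)
  grown to ≥ 5 µm² (2D) or ≥ 1.2 µm³ (3D); a trunk with two children
  guarantees at least one skeleton branch point. (A 2-segment chain has no
  degree-3 node, so trees start at 3 segments.)
* **unbranched** — a gently curved tube, width 0.3–0.5 µm, area 1–4 µm²
  (length capped at 7× width in 2D so aspect ratio stays ≥ 2; 3D tubes are
  1.5–3 µm long capsules of radius 0.15–0.25 µm).
* **swollen** — an ellipse/ellipsoid with axis ratio ≤ 1.35 (≤ ~1.4 in 3D),
  area 1–4 µm² (volume 0.4–1.2 µm³), giving roundness ≥ 0.7.
* **punctate** — a disc/ball of 0.3–1 µm² (≤ 0.16 µm³); the lower bound
  keeps every generated object above the particle-size filter.

Every drawn object is verified against its class-defining bounds and
redrawn if digitization violates them, so the bounds hold for every seed.
Scenes place objects with disjoint gap-padded bounding boxes (guaranteeing
the minimum gap), then add per-object signal amplitude (±15%), Gaussian PSF
blur, a constant background plus linear gradient, Poisson shot noise and
Gaussian read noise. All randomness flows from a single integer seed and
outputs are bit-reproducible.

What the generator does *not* emulate: cristae ultrastructure, out-of-focus
light beyond a Gaussian PSF, photobleaching, object overlap/contact, and the
ambiguity of hand classification near class boundaries. The class-size
bounds are drawn with deliberate margins inside the nominal definitions, so
the generated classes are geometrically separable. Passing accuracy bounds
on this data therefore demonstrates that the pipeline implements the
protocol correctly and can recover a clean signal — not that it would reach
the same accuracy on real, hand-labeled micrographs, where class overlap is
irreducible.

## Problem sizes and numerical choices

The reference protocol runs use 300 objects/class (2D, 1200 objects total)
and 200 objects/class (3D), chosen to be comfortably larger than the
hand-classified sets they stand in for while keeping a full
generate → measure → select → train → evaluate cycle in minutes on one CPU.
Degenerate inputs are handled explicitly: empty objects raise; a blob whose
skeleton is empty falls back to its central pixel; collinear point sets
bypass the hull; constant images pass through CLAHE unchanged; constant
descriptor columns z-score to zero; groups of one image report SD = 0 with
n = 1.

## Known limitations

* The 32-descriptor suite is a reconstruction (see above), not a verbatim
  copy of any plugin's output list.
* Percent-area profiles are computed from post-erosion object areas — the
  same pixels the descriptors see.
* Group statistics stop at mean ± SD; hypothesis testing is out of scope.
* No GUI annotation tooling; annotations are supplied as mask arrays, and
  pixel-classifier models persist in this package's own joblib format.
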