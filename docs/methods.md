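# Methods

## Pipeline model

`histospect` treats tissue-tile classification as a four-stage feature
pipeline: deep-feature extraction, spectral reduction, fusion + selection,
and shallow classification. The underlying assumptions are (i) tap-layer
activations of CNNs are informative but highly redundant descriptors of
tile texture; (ii) after a fixed orthogonal transform that compacts energy
into few coefficients, truncation discards mostly noise; (iii) class
information surviving in individual columns is detectable by a univariate
between/within variance ratio; (iv) the remaining low-dimensional
representation is separable by conventional kernel or discriminant
classifiers.

## Data handling

Datasets follow the class-per-subdirectory layout of public tile
collections. Labels are assigned by lexicographic subdirectory order
(deterministic across filesystems), files are read in lexicographic order,
rasters are normalized to 8-bit RGB (grayscale replicated to 3 channels).

**Resizing.** Tiles are bilinearly resized to each backbone's input
geometry: 224 × 224 × 3 for ResNet50/DenseNet201, 227 × 227 × 3 for
AlexNet.

**Stratified split.** Defaults follow the two standard presets,
train fractions 0.70 and 0.60. Per class the train count is
`round(fraction × class_size)` (half up, clamped so both partitions get at
least one sample); the global total is then reconciled to
`round(fraction × n)` by ±1 adjustments of the class currently most over-
or under-represented relative to its exact share (ties: larger class,
then lower label). This keeps every class within one sample of its exact
proportion, which a repair confined to the single largest class cannot
guarantee (e.g. class sizes 3/3/3/7 at fraction 0.5).

**Augmentation.** Training tiles (only) receive `copies_per_image`
randomized copies: independent horizontal/vertical flip coin-flips and a
rotation angle uniform in (−30°, +30°), corners filled by reflection
(boundary handling was an open choice; reflection avoids introducing a
constant-color corner class cue). `copies_per_image` defaults to 2 —
the multiplicity is a package choice, exposed in config.

## Backbones

The three architectures are defined in-repo as NumPy forward passes
(im2col convolution + BLAS matmul, strided-view pooling, inference-mode
batch norm): AlexNet tapped at the post-ReLU second fully connected layer
`fc7` (4096), ResNet50 and DenseNet201 tapped at the global average
pooling output (2048 and 1920). Tap width is an architectural constant,
so the dimension contracts are verified with seeded He-initialized random
weights — no downloads. Batch-norm layers initialize to the identity
(γ=1, β=0, zero mean, unit variance), which is exact for inference with
random weights. `weights_mode="pretrained"` is a declared mode that
raises until externally exported parameters are supplied; the package does
not bundle or fetch ImageNet weights.

**Fine-tuning** follows the frozen-extractor transfer-learning recipe:
the replacement head (a linear layer emitting `n_classes` scores) is
trained on tapped features by minibatch SGD with momentum on softmax
cross-entropy, with the stated defaults: minibatch 10, learning rate
1e-4, at most 20 epochs, momentum 0.9 (the conventional SGDM setting; the
momentum value was an open choice). The mean loss per epoch is logged;
the shuffling seed makes runs bit-reproducible. A `validation_fraction`
key (default 0.1) is exposed for callers who hold out training data, and
is not exercised by the core pipeline.

**`dct_energy` pseudo-backbone.** A hand-crafted, weight-free extractor
(absolute values of the leading zigzag-ordered 2-D DCT coefficients of
tile luminance) registered alongside the CNNs so the full pipeline runs at
desk scale. It is synthetic/diagnostic, not one of the CNN backbones, and
is labelled as such in its module.

## Spectral reduction and fusion

The orthonormal DCT-II is used throughout (normalization was unstated in
the design space; orthonormality gives Parseval energy conservation, exact
invertibility at full length, and monotone truncation error, all of which
are tested). Reduction is applied **per sample along the feature axis**
with nothing fitted across the dataset, so train/test leakage is
structurally impossible and row permutation commutes with the transform.

Two coefficient-selection modes exist because applying "zigzag scanning"
to a 1-D feature vector is ambiguous:

* `one_d` (default): DCT-II of the row, keep the first `N_keep`
  coefficients — the unique parameter-free reading, where zigzag on a
  one-row grid degenerates to natural order;
* `two_d`: reshape the row into a `ceil(sqrt(N)) × ceil(N/rows)` grid
  (zero-padded tail), separable 2-D DCT-II, JPEG zigzag read-out
  (anti-diagonals, alternating direction, starting (0,0), (0,1)), keep the
  first `N_keep`.

The mode is a config key, not a hidden default. Default per-backbone
retained counts are 1500 (AlexNet), 1200 (ResNet50), 1000 (DenseNet201);
fusion concatenates parts in the declared order (recorded in metadata) and
reduces to 4000 coefficients by default, ≈50% of the 8064-wide
concatenation of the three CNNs.

## ANOVA selection

Per feature `j`: `SSB_j = Σ_g n_g (m_gj − m_j)²`,
`SSW_j = Σ_g Σ_{i∈g} (x_ij − m_gj)²`,
`F_j = (SSB_j/(G−1)) / (SSW_j/(n−G))`. Degenerate conventions:
`SSW = 0, SSB > 0` → `+inf` sentinel (ranks above all finite scores);
`SSB = SSW = 0` → 0. Ties (including among sentinels) break toward the
lower feature index, making selection deterministic. Scores are fitted on
the training partition only; `apply_selection` restricts any
equal-width matrix with the train-fitted indices. Selection is by count
(top-k over the grid {1000, 1500, 2000, 2500} by default), not by
p-value. The grid sweep is exposed as-is; no nested validation is layered
on top of it.

## Classifiers

**Cubic SVM** — the common preset: degree-3 polynomial kernel, `C = 1`,
`coef0 = 1`, kernel scale `1/(d · Var[X])`, one-vs-one multiclass,
inputs standardized with train-partition statistics (zero-variance columns
get unit scale). Backed by `sklearn.svm.SVC`. For ROC the per-class
one-vs-rest decision values are squashed through a logistic to [0, 1]
(monotone, so AUC is unchanged by the map).

**ESD (ensemble subspace discriminant)** — `n_learners = 30` regularized
linear discriminants, each on a seed-controlled random feature subset of
size `ceil(d/2)` drawn without replacement; prediction is the argmax of
mean class posteriors (rows sum to 1). The pooled within-class covariance
is shrunk toward its own diagonal (`shrinkage = 0.1`) plus a tiny trace
jitter, keeping it invertible in the wide-matrix d > n regime deep
features occupy. The composition (learner count, subspace size,
aggregation) follows random-subspace conventions — these are package
choices, exposed in `EsdSpec`. With one learner, full subspace and zero
shrinkage the model coincides with a standard pooled-covariance LDA, which
is cross-checked against scikit-learn's implementation in the tests.

## Evaluation

Per class one-vs-rest counts come off the confusion matrix
(`TP = cm[i,i]`; `FN`/`FP` the remainders of row/column `i`; `TN` the
rest), feeding accuracy `(TP+TN)/n`, sensitivity `TP/(TP+FN)`,
specificity `TN/(TN+FP)`, precision `TP/(TP+FP)` and
`F1 = 2TP/(2TP+FP+FN)`. Note the per-class one-vs-rest accuracy is a
different quantity from the overall accuracy `trace(cm)/n`; both are
reported. A 0/0 denominator yields 0 with a `RuntimeWarning` (degenerate
class convention). Macro summaries use the arithmetic mean and the
*population* SD (divide by G — the divisor was an open choice). AUC is
per class one-vs-rest by mid-rank (Mann–Whitney), which equals the
pairwise concordance count with ties scored ½ — verified exactly against
an O(n²) oracle. No micro-averaged AUC is reported.

## Synthetic generators

`generate_texture_dataset` renders per-class sinusoidal gratings
(distinct orientation/frequency per class, defaults spread over [0, π)
and a frequency ladder from 0.06 cycles/px) plus Gaussian noise
(SD 0.05 on the [0,1] scale by default) at 150 × 150 px — the tile
geometry of public texture collections. Gratings were chosen over random
textures deliberately: spectral-energy features separate them by
construction, so the end-to-end pipeline is testable without learned
weights. `generate_feature_table` plants `n_informative` columns with
per-class mean offsets `(g − (G−1)/2) · effect_size` (adjacent classes
differ by `effect_size` pooled SDs, default 2, 3 classes) among standard
normal noise and returns the ground-truth index set.

What passing desk-scale tests shows: the transforms, selection, training
and metric code are correct, deterministic and leakage-free on inputs with
known structure. What it does not show: performance on real H&E tiles,
which have stain variation, morphological (not purely spectral) class
cues, and class-dependent covariance — none of which the gratings
emulate.

## Problem sizes and numerical choices

The default test and acceptance workloads use 4 classes × 60 tiles,
pseudo-backbone widths 1024/576/256, fusion to 928 (50%), ANOVA k = 200,
and 2-image batches through the randomly initialized CNNs — sizes chosen
so the full suite exercises every stage in well under a minute of compute
while keeping every contract (widths, determinism, accuracy ≥ 0.90)
meaningful. Tolerances: DCT vs direct summation 1e−12 (N ≤ 64); Parseval
and inversion 1e−9; ANOVA vs naive oracle 1e−10; AUC vs pairwise oracle
exact to 1e−12. Degenerate inputs (constant features, empty matrices,
single-sample classes, absent classes in AUC) follow the conventions
stated above rather than erroring where a convention exists.

## Known limitations

* Pretrained weights are not bundled; reproducing published full-dataset
  accuracies (e.g. the ~96.8%/99.3% regimes reported for the public
  Kather and NCT collections) requires downloading those archives and
  ImageNet-pretrained backbones, then running the `exp4` preset — an
  out-of-suite check by design.
* Fine-tuning updates the classification head only; full backpropagation
  through the convolutional stacks is out of scope.
* Stain normalization, whole-slide tiling, explainability overlays and
  alternative backbones/transforms are out of scope.
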