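# Methods

`hyperleaf` implements a complete hyperspectral leaf-disease identification
pipeline — reflectance calibration, leaf segmentation, spectral
preprocessing, wavelength selection, classical classification, and a family
of lightweight spectral–spatial CNNs — together with a seeded synthetic
leaf simulator that provides ground truth for every stage. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Reflectance calibration

Raw line-scan intensities are converted to reflectance with the standard
white/dark correction

    R = (I_raw − I_dark) / (I_white − I_dark),

element-wise over the cube. The white reference is a scan of a ≥99 %
reflectance standard; the dark reference is acquired with the lens capped.
References may be full cubes or per-band row profiles broadcast across scan
lines (line-scan practice). Denominators with |white − dark| < 1e−6 are
zeroed and counted; if more than 1 % of elements are degenerate the
calibration is refused. The correction is invariant under affine sensor
transforms (gain/offset), which the test suite verifies directly.

Cubes are stored H×W×B (band-last), little-endian float32, with ENVI
header/binary I/O (BSQ and BIL interleaves; wavelengths serialized at four
decimals). The working wavelength axis is 761 uniform points on
400–1000 nm; a 995-point 305–1090 nm axis stands in for the full sensor in
cropping tests (the native band count of such sensors varies by binning;
the number here is a fixture, not an instrument claim).

## Segmentation and dataset preparation

Leaves are bright on the NIR plateau while the imaging background is dark,
so segmentation thresholds the band nearest 800 nm with Otsu's method
(between-class variance maximization over a 256-bin histogram spanning
[min, max]; ties resolve to the lowest cut). The foreground is the side of
the threshold with the higher mean reflectance; cleanup keeps the largest
8-connected component and fills holes — cleanup is standard practice rather
than part of the threshold definition.

Mean spectra are per-band arithmetic means over the mask. For CNN work,
leaves are split into k ∈ {2,3,4} overlapping sub-blocks along the longer
bounding-box axis (k chosen by long-axis length: <150 px → 2, <250 → 3,
else 4). Window length starts at ceil(L / (k − (k−1)·0.25)) with uniformly
spaced starts; the length backs off by single pixels if integer rounding
would push any pairwise shared-length fraction to the 30 % cap, so the
overlap constraint holds strictly for every admissible L. "Overlap" means
shared window length divided by window length.

ROIs are zero-padded into centered 112×112 frames (background zeroed;
oversized ROIs are nearest-neighbor downscaled preserving aspect).
Augmentation draws uniformly from the eight-element dihedral group
restricted to the six non-identity ops {horizontal flip, vertical flip,
rotations by 90/180/270°, transpose}; ops touch spatial axes only, never
the spectral axis, and originals are always retained.

Partitioning is stratified by class at the leaf level (largest-remainder
rounding keeps every class within one leaf of exact 60:20:20). Sub-blocks
and augmented copies inherit their parent leaf's fold — splitting happens
after partitioning, which is the leakage rule the whole pipeline enforces
and the integrity tests check end-to-end.

## Spectral preprocessing and wavelength selection

SNV (standard normal variate) centers and scales each spectrum to unit
sample standard deviation (n−1 denominator), removing multiplicative
scatter and additive baseline; rows with standard deviation below 1e−12
are rejected by name.

All multi-class chemometrics use the PLS2 convention: labels become one-hot
responses, one NIPALS PLS2 model (sklearn backend, no scaling) regresses
all six columns, class decisions take the argmax, and variable importance
is the row L2 norm of the p×K coefficient matrix. sklearn centers X
internally in `predict`; the exported coefficient/intercept pair folds
that centering in, so `X @ B + intercept` is exact (a property pinned by
an oracle test against the normal equations).

**CARS** (competitive adaptive reweighted sampling) runs N Monte-Carlo
iterations (default 50; the number of runs is configurable and published
runs are often in the thousands). Each run draws ⌈0.8·n⌉ calibration rows,
fits PLS2 on the surviving variables, and normalizes the coefficient row
norms to weights. The exponentially decreasing function enforces
⌈r_i·p⌉ survivors with r_i = a·e^(−k·i), a = (p/2)^(1/(N−1)),
k = ln(p/2)/(N−1) — run 1 keeps all p, run N keeps 2, monotonically.
Adaptive reweighted sampling then draws ⌈r_i·p⌉ times with replacement
(weights as probabilities); variables drawn at least once survive, so ARS
can only shrink a run's subset. Each run's subset is scored by stratified
5-fold RMSECV (pooled over response columns); the minimum wins. The PLS
component count is chosen once on the full matrix by 5-fold RMSECV over
1–10 and held fixed across runs. Runs whose subset falls below two
variables score +Inf.

**SPA** (successive projections algorithm) builds, from every starting
column, a chain of up to 30 variables, each step appending the column with
the largest norm in the orthogonal complement of the span of the chosen
ones (computed on column-centered data; chains truncate on numerically
zero projections). Every (chain, size) is scored by intercept-MLR on
one-hot responses, RMSEP on a held-out validation fold; ties across starts
resolve to the lowest start index. The final size may shrink to the
smallest m whose squared-RMSEP ratio to the minimum passes an F-test at
α = 0.25 (degrees of freedom = number of validation residuals), following
the original SPA practice of preferring the smallest statistically
equivalent subset.

A note on what "recovering planted bands" can mean: when spectra carry
multiplicative scatter — or after SNV, which injects the class-dependent
row mean into every band — bands outside the planted windows become
genuinely informative (they act as internal reference bands), and
minimum-RMSECV subsets legitimately retain them. The selector-recovery
experiments therefore use the simulator's scatter-free spectra, where the
planted windows are the only signal; with scatter on, retention of
reference bands is expected behavior, not a selector failure. The pipeline
default for real spectra remains SNV before selection.

**Classifiers.** PLS-DA grid-searches the component count (1–20) on
validation accuracy, ties to the smaller count. The RBF-SVM (one-vs-one)
grid-searches C ∈ 2^{−5..15} and γ ∈ 2^{−15..3} (step 2 in the exponent),
ties to smaller C then smaller γ, on SNV-corrected spectra.

## CNN architectures

All five architectures take 112×112×N reflectance inputs (N ≥ 8 for 3D
stems; any N for 2D), clipped to [0, 2] with no per-image standardization.

**hybrid_lcnet (3D-2D)** — input laid out (1, N, 112, 112):
two 3×3×3 convolutions (1→16→32, stride 2 on every axis, zero-pad 1, each
with BN+ReLU) bring a 30-band cube to (32, 8, 28, 28) (a 15-band cube to
depth 4); adaptive average pooling collapses the spectral axis to 2
(spatial untouched); the volume is regrouped to 64 channels at 28×28; four
ShuffleNetV2 units follow — downsample 64→128 (stride 2, to 14×14), basic
128, downsample 128→256 (to 7×7), basic 256 — then 1×1 conv to 512 with
BN+ReLU, global average pooling, dropout 0.2, and a linear classifier.
Convolutions are bias-free when followed by BN; the final linear has a
bias. The stem widths 16/32 are the unique choice consistent with the
64-channel 28×28 bridge (32 channels × pooled depth 2) and with the
0.26 M parameter budget the architecture must land on.

ShuffleNetV2 units are the standard construction: the basic unit splits
channels half/half, passes one half through, runs the other through
1×1 (BN+ReLU) → 3×3 depthwise (BN) → 1×1 (BN+ReLU), concatenates and
channel-shuffles with two groups; the downsampling unit feeds the full
input to both branches (left: strided depthwise then 1×1; right: 1×1,
strided depthwise, 1×1), so concatenation re-targets the channel count.
Channel shuffle is the fixed permutation reshape-(2, C/2)-transpose-
flatten, a bijection on channel indices.

**lcnet3d** — identical stem, pooling, channel widths and head, but the
four units and the head are genuine 3D operators (3×3×3 depthwise, 1×1×1
pointwise, strides (1,2,2)) on the pooled volume with the spectral content
folded into channels exactly as in the hybrid. This makes the two models
differ by precisely the depthwise-kernel inflation (27 vs 9 weights per
channel): 270,550 vs 260,182 parameters, i.e. 0.27 vs 0.26 M at two
decimals. Keeping the pooled depth as a separate length-2 axis is
incompatible with that parameter relationship (the pointwise convolutions
would see 32 channels, not 64), so the channel-folded form is the one
implemented.

**lcnet2d** — bands-as-channels input (N, 112, 112); stem 3×3 convs
N→16→64, both stride 2; then the same four units and head (259,526
parameters — a minimal 2D counterpart, as the 2D variant admits several
equally plausible stems).

**shufflenetv2_2d / _3d** — the reference lightweight baseline at width
multiplier 0.25: stem 3×3 stride-2 conv to 24 channels, 3×3 stride-2
max-pool, stages of 32/64/128 channels with 4/8/4 units (one downsampling
unit opening each stage), head 1×1 conv to 1024, global pool, classifier.
The 3D variant strides the spectral axis only in the stem; stage strides
are (1,2,2).

**Accounting.** Parameter counts are reported two ways and must agree
exactly: the framework sum over parameter arrays, and an independent
closed-form layer sum (convs: kernel-volume × C_in × C_out, ÷C for
depthwise; BN: 2C; linear: C_in·C_out + C_out). FLOPs are reported as
2 × multiply-accumulates of convolution and linear layers only for one
input (BN and activations excluded); the convention is embedded in every
report because published counters differ in it, which is why printed FLOP
totals are not comparable across toolchains.

**Training protocol.** Adam with library defaults, cross-entropy, initial
learning rate 1e−3 halved every 20 epochs (so exactly 5e−4 at epoch 21,
2.5e−4 at 41), batch 64, 200 epochs, best-validation-accuracy checkpoint
returned; every stochastic element (shuffling, dropout, initialization) is
seeded, and equal seeds reproduce the history bit-for-bit. The repeated
protocol freezes the 20 % test fold, re-splits the remaining 80 % into
60/20 five times (stratified at the leaf level), and reports mean ± sd per
architecture plus Dunn–Bonferroni pairwise comparisons.

The layers themselves (N-d convolution via im2col/GEMM with an analytic
col2im backward, fused BN(+ReLU), ShuffleNetV2 units, Adam) are
implemented in numpy with numba-compiled data-movement kernels; every
layer's backward pass is validated against float64 central differences.

## Evaluation

Per-class metrics collapse the K×K confusion matrix one-vs-rest:
accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Macro values are unweighted class means; overall accuracy is trace/total;
0/0 terms are defined as 0 with a warning; the multi-class MCC is the
macro mean of per-class binary MCC, consistent with macro P/R/F1. AUC is
the midrank Mann–Whitney statistic per class one-vs-rest, macro-averaged,
with absent classes excluded under a warning. Dunn's test computes pooled
midranks with tie correction, pairwise z statistics, Bonferroni adjustment
(p × n_pairs, capped at 1), and a compact letter display (groups sorted by
median; a group joins a letter if not significantly different from every
member).

## The synthetic leaf simulator

Templates follow green-vegetation phenomenology: low blue shoulder
(~0.06 at 450 nm), green peak (~0.15 at 550 nm), chlorophyll trough
(~0.05 at 680 nm), logistic red edge centered at 715 nm, NIR plateau
(~0.48). Six condition classes modify the baseline: nitrogen deficiency
adds a chlorosis bump (Gaussian at 555 nm, width 45 nm) in the 500–680 nm
window, pesticide damage a browning bump at 645 nm, each +0.05 alone and
+0.065 when combined with infection; CYVCV infection subtracts 0.06 on the
750–1000 nm plateau. Healthy and CYVCV-only leaves are the darkest in the
chlorophyll window; infected classes are darkest on the NIR plateau —
the qualitative ordering observed in the field. The shape (not merely
magnitude) differences matter: if stressed classes differed only by
visible-offset magnitude, the six class means would be nearly collinear
and one-hot linear regression (PLS-DA) would mask the middle classes —
a known failure mode of regression-to-indicators — so stress *type* is
encoded spectrally, as it is in real leaves. Amplitudes are stand-ins
chosen for clear separability, not measurements; a "hard mode" (offsets
halved, jitter doubled) exercises the confusion structure qualitatively.

Leaf images place the class template on an elliptical mask (axis ratio
1.4–2.6, random orientation, sinusoidal boundary perturbation) over a
near-zero background (~0.02), modulated by a smooth ±10 % brightness field
plus per-pixel Gaussian jitter (sd 0.02). Mean spectra over the true mask
stay within 0.02 of the template per band, and the 800 nm contrast
guarantees Otsu separability. Dataset defaults reproduce the six-class
field design: 522 leaves with per-class counts 90/90/79/81/90/92.
Mean-spectrum fixtures add leaf-level window offsets (sd 0.005), band
noise (sd 0.006) and, optionally, multiplicative/additive scatter
(a ~ N(1, 0.05), b ~ N(0, 0.01)) — the component SNV exists to remove.

**What passing means.** The simulator produces spectrally clean,
well-separated classes on simple shapes; it does not model venation,
lesions, specular highlights, radiative transfer, sensor noise physics, or
the overlapping class distributions of field data. Accuracies near 1.0 on
the default configuration therefore validate the *machinery* (shapes,
gradients, selection logic, leakage rules), not field performance; the
published field-data accuracies live in the 69–97 % range precisely
because real classes overlap.

## Problem sizes used in the shipped experiments

The shipped test suite and acceptance script run at desk scale, chosen as
the package's own experiment design: selector recovery uses 300 spectra ×
761 bands × 5 seeds (CARS with 50 Monte-Carlo runs); classifier sanity
uses 300 spectra with the full SVM grid; the CNN experiment trains
hybrid_lcnet on 600 simulated 112×112×15 leaves (60/20/20 split) for 15
epochs at batch 16, five seeds, reporting the median test accuracy; the
architecture audits build all five networks for 15- and 30-band inputs.

## Known limitations

- The numpy/numba engine targets correctness and single-core CPU use; it
  has no GPU path and trains at desk scale only.
- The ShuffleNetV2 comparison baselines follow the published width-0.25
  recipe, but the original's exact BN momentum/epsilon and initializer are
  not reproduced — parameter counts match, trained accuracies need not.
- SPA evaluates all p starting columns; for p much larger than ~10³ the
  quadratic cost would warrant a subsampled start set.
- The compact letter display uses a greedy insertion algorithm; for many
  groups with tangled significance patterns it can emit more letters than
  the minimal covering.
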