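# Methods

## Model

DSF-Net and DSA-Net are shallow fully convolutional per-pixel classifiers
for vessel/background segmentation of RGB fundus images. Shared layout:

    input block → (stream A ∥ stream B) → merge → final block
                → decoder (2 transposed convs) → 1×1 classifier → softmax

* Every 3×3 convolution is followed by batch normalization then ReLU and
  carries no bias (the BN shift absorbs it exactly).
* Stream A downsamples twice by stride-2 convolution; stream B twice by
  2×2 max pooling (average pooling is a config option). Both maps
  n → ceil(n/2), so the merged feature for an H×W input sits at
  (ceil(ceil(H/2)/2), ceil(ceil(W/2)/2)) — 163×163 for 650×650. Inputs
  are processed at native size; nothing is resized.
* Merge: DSF adds the stream outputs element-wise; DSA concatenates them
  depth-wise (256+256 → 512) and lets the first final-block convolution
  act as a bottleneck.
* Decoder: two kernel-4, stride-2, pad-1 transposed convolutions
  (each + BN + ReLU), giving exactly 4× upsampling; the result is
  center-cropped to the input size (e.g. 163→326→652→crop 650).
* Classifier: 1×1 convolution to 2 channels + per-pixel softmax.
  Binarization is the argmax with ties resolved to background, equivalent
  to thresholding the vessel probability at 0.5 — the conservative choice
  for false positives.

### Channel schedule and parameter budget

The architecture's structural contract is: exactly nine 3×3 convolutions,
both streams ending at depth 256, and *identical* trainable-parameter
totals for the two variants, rounding to 1.5 M. The layer-by-layer
channel table needed to reproduce this is not fully pinned down by the
contract, so the reference schedule here was solved from it directly:

| block       | DSF            | DSA            |
|-------------|----------------|----------------|
| input       | 16, 32         | 16, 32         |
| stream A    | 64 (s2), 256 (s2) | same        |
| stream B    | 64 +pool, 256 +pool | same      |
| final       | 256, 192, 64   | 128, 320, 64   |
| decoder     | 32, 16 (transposed) | same      |

The DSA bottleneck 512→128 has the same weight count as DSF's 256→256
(3·3·512·128 = 3·3·256·256), and the remaining final-block widths solve
the weight-balance and BN-channel-balance equations exactly
(9·(256·192 + 192·64) = 9·(128·320 + 320·64) and 256+192 = 128+320), so
both variants count **1,523,090** trainable scalars — not merely equal
after rounding. `count_parameters` verifies this at build time in the
tests; `count_conv3x3` counts only 3×3 layers (the 1×1 classifier and the
transposed convolutions are excluded from the nine).

### Initialization and normalization

Convolutions use He-uniform initialization from a seeded generator (the
networks are trained from scratch; no pretraining or transfer). BN uses
eps 1e-5 and momentum 0.1 on running moments. One deliberate deviation
from common practice: while a BN layer has never seen a training batch,
inference falls back to the statistics of the batch at hand. Freshly
initialized running moments (0/1) bear no relation to real activation
distributions, and an untrained network evaluated through them saturates
into a near-constant class map; the fallback keeps untrained predictions
calibrated, which makes "trained beats untrained" comparisons meaningful.

## Loss

Generalized Dice loss over the softmax probabilities with squared-inverse
class-volume weights w_l = 1/(Σ_n r_ln)², computed per batch. A class
absent from the reference would get infinite weight; its weight is capped
at 1e8 (configurable). The loss lies in [0,1], is 0 exactly at one-hot
agreement, and is invariant to duplicating all pixels. The analytic
gradient w.r.t. the probabilities is chained through the softmax in the
training loop; both are finite-difference checked in the tests.

## Training regime

Adam (β1 0.9, β2 0.999, eps 1e-6), initial learning rate 1e-4, 35 epochs,
per-epoch reshuffling, and global L2 gradient normalization — read here
as clipping the global gradient norm to a threshold (default 1.0), the
standard interpretation of that phrase. Batch size defaults to 12, the
value implied by the published bookkeeping (3840 augmented training
images / 320 iterations per epoch; 35 epochs → 11,200 iterations, which
`planned_iterations` reproduces exactly). No validation split or early
stopping: a fixed epoch budget. Training is bit-reproducible per seed on
one device; non-finite losses abort with the iteration index.

The engine is hand-written numpy: convolutions run as shift-and-accumulate
GEMMs (one (C_in, C_out) product per kernel offset over contiguous
shifted copies), transposed convolutions and input gradients share a
dilate-then-correlate routine, and max-pool backward scatters through
stored argmax indices. float32 is used for training; the gradient-check
tests run the identical code in float64.

## Synthetic data

`vesselseg.synth` generates image/mask pairs with the statistics the
segmenter assumes: a bright reddish FOV disc on a near-black border,
radial+linear illumination gradient, a dark branching vessel tree,
optional bright centerline (central vessel reflex), Gaussian blur, and
additive Gaussian noise. The tree is a recursive branching random walk:
per-step heading jitter (tortuosity 0.18 rad), per-branch width decay
(0.72), bifurcation probability 0.06 per step, roots on the FOV rim.
Trees are added until the vessel fraction inside the FOV reaches a target
(default 0.10, matching the ~0.09 vessel ratio of real retinal images),
so the fraction is essentially exact across seeds; overshoot is bounded
by one painted step. Defaults: 128×128 for CPU work, a 512×512 preset
with reflex enabled for visual inspection.

What the generator does **not** emulate: lesions (hemorrhages, exudates),
the optic disc and macula, artery/vein distinction, camera vignetting
beyond a smooth gradient, JPEG artifacts, or inter-grader annotation
noise. Passing the synthetic-data checks therefore demonstrates that the
implementation can learn and segment under the assumed image model, not
that it matches published accuracy on DRIVE/STARE/CHASE-DB1 — that would
require the external datasets and long training.

### Desk-scale preset

The end-to-end learning check trains DSA-Net on 200 synthetic 128×128
pairs for 5 epochs. Its optimizer preset (`desk_config`) uses batch 4 and
learning rate 2e-3: the published 1e-4 is calibrated to an 11,200-step
budget, and a 250-step run needs a proportionally larger step size. The
check requires held-out mean Dice ≥ 0.75 and SE ≥ 0.70 and strict
improvement over an untrained network on every reported metric.

## Metrics and screening

Acc/SE/SP come from pixel confusion counts; AUC is the trapezoidal ROC
area of the vessel-class probability (Mann–Whitney midpoint convention
for ties, delegated to scikit-learn and cross-checked against a
brute-force pairwise oracle); the paired two-tailed t-test delegates to
scipy with an explicit zero-variance guard. Metrics are computed over all
pixels by default with an optional FOV restriction, and reports give
per-image rows plus an unweighted mean row (the aggregation convention is
documented as the mean because no pooling rule is otherwise fixed).

V_r is vessel/background pixel counts of a binary mask, full-image by
default (the reference worked example uses all 329,960 pixels of a
565×584 mask: 26,566 vessel, 303,394 background, V_r = 0.0876). Visit
comparison uses *relative* change with a default 5% threshold — raw
inequality would flag noise — and emits an "indicative" direction, not a
diagnosis. The claim that V_r is robust to acquisition conditions is a
motivation, not an invariant this package asserts.

## Data handling

Catalogs are described by a TSV manifest (id, image, mask, split);
DRIVE-style GIF masks and multi-frame decodes are handled. Masks binarize
at grayscale ≥128 by default (expert masks are near-binary). Augmentation
is a deterministic flip × translation product; the DRIVE preset (4 flips
× 48 translations: the 7×7 lattice of ±15 px step 5 minus one corner)
expands 20 images to 3840. The published counts 3840/1344/1210 from
20/19/14 images imply mutually inconsistent per-image factors
(192/70.7/86.4), so no single grid can reproduce all three; the preset is
a documented reconstruction of the DRIVE count only.

## Known limitations

* Single-device, single-precision training only; no mixed precision, no
  GPU, no hyperparameter search.
* The comparison networks (SegNet, U-Net, Vess-Net, AA-UNet, VSSC Net)
  are not implemented; parameter-reduction figures quote their published
  sizes.
* Checkpoints store exact arrays (bit-exact round trip) but serialized
  file size is not a contract.
* The desk-scale learning bar is evidence of correct optimization, not of
  clinical-grade segmentation.
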