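# vesselseg

Shallow dual-stream networks for retinal blood-vessel segmentation in
fundus photographs, with a vessel-ratio statistic for longitudinal
diabetic/hypertensive retinopathy screening.

Accurate maps of the retinal vasculature are a primary biomarker for
systemic disease: diabetic retinopathy inflames and thickens vessels,
hypertensive retinopathy narrows them. `vesselseg` is aimed at
researchers who need a small, fully inspectable, CPU-trainable
segmentation stack — every layer, gradient and optimizer step is plain
numpy — rather than a large pretrained model.

## The networks

Both networks are encoder–decoder semantic segmenters that classify every
pixel as vessel or background. One small convolutional input block feeds
two parallel encoder streams:

* **Stream A** downsamples with *strided* 3×3 convolutions (no pooling);
* **Stream B** uses stride-1 3×3 convolutions followed by 2×2 max pooling.

Their outputs G and K (equal shape, depth 256) are merged:

* **DSF-Net** (dual-stream fusion): `S_Res = G ⊕ K` (element-wise addition);
* **DSA-Net** (dual-stream aggregation): `S_Dense = G © K` (depth-wise
  concatenation to 512 channels, then a bottleneck convolution).

A final convolutional block refines the merged feature and a two-layer
transposed-convolution decoder restores input resolution for a per-pixel
two-class softmax trained with the **Generalized Dice Loss**

    GDL = 1 − 2 · Σ_l w_l Σ_n r_ln p_ln / Σ_l w_l Σ_n (r_ln + p_ln),
    w_l = 1 / (Σ_n r_ln)²,

whose squared-inverse class-volume weights keep the ~9% vessel class from
being swamped by background. Spatial bookkeeping is ceil-mode throughout,
so a 650×650 image reaches the merge at 163×163. The reference schedules
use exactly **nine 3×3 convolutions** and **1,523,090 trainable
parameters (≈1.5 M)** — identical for both variants by construction.

Evaluation uses pixel accuracy, sensitivity SE = TP/(TP+FN), specificity
SP = TN/(TN+FP), ROC AUC of the vessel-probability map, and Dice overlap;
models are compared with a paired two-tailed t-test on per-image metrics.

The screening statistic is the **vessel ratio** `V_r = vessel pixels /
background pixels` of a predicted mask. Across visits of one patient, a
relative rise beyond a threshold (default 5%) is flagged as
diabetic-indicative, a fall as hypertensive-indicative.

## Worked example

```python
import numpy as np
from vesselseg import DualStreamSegmenter, vessel_ratio, compare_visits
from vesselseg.synth import VesselTreeParams, generate_dataset

pairs = generate_dataset(40, VesselTreeParams(size=64), seed=0)
X = np.stack([p.image for p in pairs]); y = np.stack([p.mask for p in pairs])

est = DualStreamSegmenter(variant="dsa", learning_rate=2e-3,
                          epochs=10, batch_size=4, random_state=0)
est.fit(X[:32], y[:32])
print("held-out mean Dice:", round(est.score(X[32:], y[32:]), 3))

rec = vessel_ratio(est.predict(X[32:33])[0], patient_id="p1", visit="v1")
print("V_r:", round(rec.v_r, 4))
```

prints (CPU, ~2 minutes):

```
held-out mean Dice: 0.698
V_r: 0.113
```

i.e. after only 80 optimizer steps the model already overlaps ~0.7 of the
reference vessel pixels, and the predicted mask's vessel-to-background
ratio sits near the generator's true ~0.11 (vessel fraction 0.10 of the
field of view). The acceptance-scale run (200 images at 128×128, 5
epochs) reaches held-out mean Dice ≈ 0.86. The same pipeline is
available from the shell:

```bash
vesselseg synth --n 40 --size 64 --seed 0 --out data/
vesselseg train --manifest data/manifest.tsv --net dsa --out run/
vesselseg segment --checkpoint run/model.npz data/images/*.png --out masks/
vesselseg evaluate --checkpoint run/model.npz --manifest data/manifest.tsv --out eval/
vesselseg screen --mask masks/synth_00000_mask.png --patient p1 --store p1.csv
```

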