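# cytoscreen

Two-stage screening of cytopathology images for malignant cell clumps,
robust to staining style.

Cytology slides are scanned as gigapixel whole-slide images, cut into
1024×1024 tiles, and filtered so only tiles with tissue survive (pixel
mean in [50, 230] and standard deviation above 20, pooled over RGB).
Screening then proceeds in two stages:

1. **Segmentation** — a nested U-Net over a triangular node grid
   x<sup>i,j</sup> with dense skip connections,

   x<sup>i,0</sup> = H(D(x<sup>i−1,0</sup>)),  x<sup>i,j</sup> = H([x<sup>i,0</sup>, …, x<sup>i,j−1</sup>, U(x<sup>i+1,j−1</sup>)]),

   a channel-attention bottleneck E<sub>b</sub> = β Σ<sub>a</sub> M<sub>ba</sub> x<sub>a</sub> + x<sub>b</sub>
   (M row-softmaxed channel affinities, β learned from 0), deep
   supervision through α-weighted side heads, and a hybrid per-pixel
   loss −(1/N) Σ<sub>c,n</sub> [t log p + 2tp/(t²+p²+ε)] combining cross
   entropy with a soft Dice term (minimum −1 at a perfect prediction).

2. **Classification** — each segmented clump is cut out with its
   background zeroed, centred on a square zero canvas, and classified
   benign/malignant by a convolutional encoder trained with
   cross-entropy plus a label-supervised contrastive loss
   L = L<sub>cla</sub> + β·L<sub>con</sub> (β = 0.5, temperature τ = 0.07).
   Contrastive keys come from a momentum encoder
   (θ<sub>k</sub> ← m·θ<sub>k</sub> + (1−m)·θ<sub>q</sub>, m = 0.9) and live with their
   labels in a FIFO memory bank, so two clumps with the same label are a
   positive pair regardless of staining palette.

The networks run on a small numpy reverse-mode autodiff backend that
ships inside the package (`cytoscreen.nn`), sized for CPU-scale
experiments. A seeded synthetic-tile generator (`cytoscreen.synthgen`)
renders textured elliptical clumps — benign with neat edges, malignant
with irregular protruding edges — in H&E-like and Papanicolaou-like
palettes with exact ground-truth masks, so the whole pipeline is
trainable and testable without any slide data.

## Worked example

```python
import numpy as np
import cytoscreen as cs
from cytoscreen.roiex import rois_from_record

spec = cs.SynthSpec(tile_size=128, n_clumps=(1, 4), clump_radius=(10, 24),
                    stain_style="mixed", seed=0)
recs = [cs.generate_tile(spec, s) for s in range(200)]
images = np.stack([r.image.pixels for r in recs])
masks = np.stack([r.mask for r in recs])

model = cs.CellClumpSegmenter(depth=2, base_channels=8, batch_size=8, seed=0)
res = model.fit(images[:160], masks[:160], epochs=8,
                val_images=images[160:], val_masks=masks[160:])
print(res.summary())
```

prints (about three minutes on one CPU):

```
Cell-clump segmentation fit
============================================
depth: 2   base channels: 8
channel attention: True   deep supervision: True
optimizer: Adam(lr=0.005)   batch size: 8
epochs run: 8
final training loss: -2.3680
validation Dice: 0.9729
```

The training loss approaches its analytic minimum (−1 per supervised
head times the head weights) as predictions sharpen; the validation
Dice of 0.97 means predicted clump masks overlap the ground truth
almost perfectly on held-out tiles. Classification works the same way:

```python
roi_spec = cs.SynthSpec(tile_size=192, n_clumps=(2, 4), clump_radius=(18, 34),
                        stain_style="mixed", seed=1)
rois = [r for s in range(80)
        for r in rois_from_record(cs.generate_tile(roi_spec, 1000 + s),
                                  min_area=32, canvas=128)]
clf = cs.ClumpClassifier(input_size=64, embed_dim=64, batch_size=16,
                         bank_capacity=512, seed=0)
fit = clf.fit(rois[:175], epochs=30, seed=0)
acc = fit.evaluate(rois[175:], [r.label for r in rois[175:]])
```

yields a held-out accuracy of about 0.99 on the mixed-stain split;
with the contrastive term disabled (`beta_loss=0`) the same experiment
is consistently worse, which is the point of the labeled memory bank.

A `cytoscreen` command-line tool wraps the same objects
(`generate`, `tile`, `train-seg`, `segment`, `extract-rois`,
`train-cls`, `classify`, `evaluate`, `crossval`, `screen`); run
`cytoscreen --help` for the subcommands.

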