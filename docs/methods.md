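# Methods

## Problem setting

Cytology screening asks, for every microscope tile of a stained slide:
where are the epithelial cell clumps, and is any of them malignant?
Two staining protocols dominate clinical practice — H&E (pink/purple)
and Papanicolaou (blue/green) — and a useful screening model must not
confuse palette with pathology. The package implements a two-stage
pipeline: segment clumps first, then classify each extracted clump,
with the classifier explicitly encouraged to treat same-label clumps
from different palettes as similar.

## Stage 1: nested-U-Net segmentation

The segmenter is a nested U-Net over a triangular grid of nodes
`x[i][j]`, row `i = 0..d` halving the spatial resolution `i` times.
The encoder chain is `x[i][0] = H(D(x[i-1][0]))`; every decoder node
concatenates all same-row predecessors with one upsampled node from the
row below, `x[i][j] = H([x[i][0..j-1], U(x[i+1][j-1])])`. `H` is a 3×3
convolution + ReLU, `D` 2×2 max pooling, `U` nearest-neighbour 2×
upsampling. A depth-`d` grid has `(d+1)(d+2)/2` nodes.

**Channel attention.** At the bottleneck (K channels) the flattened
feature map forms a K×K affinity matrix `s[b,a] = x_b · x_a`,
row-softmaxed over the source channel `a` to give `M`; the output is
the residual reweighting `E_b = β Σ_a M_ba x_a + x_b` with the scalar
`β` a learned parameter initialized at 0, so the module starts as the
identity and attention is blended in only as far as it helps. A
`literal_eq2` flag switches to a variant whose softmax normalizer uses
only the diagonal self-affinity `x_b·x_b`; its rows do not sum to one
and it exists purely so the difference between the two forms can be
tested. The standard form is the default.

**Deep supervision.** Every top-row decoder node `x[0][j]`, j = 1..d,
feeds a 1×1-convolution side head producing class logits at full
resolution (row 0 needs no upsampling). The side loss is the
α-weighted sum of per-head hybrid losses; the default weights are the
last `d` entries of (0.1, 0.3, 0.6, 0.9), shallowest head first, so the
deepest (most context-rich) head dominates. Earlier formulations of
this module attach a global-average-pooling branch to the side path;
GAP cannot supervise per-pixel targets and is omitted here — a known
deviation, recorded as a limitation.

**Hybrid loss.** Per pixel and class,
`-(t log p + 2tp/(t² + p² + ε))`, averaged over the `N` pixels of the
batch and summed over classes. The first term is cross entropy, the
second a soft per-pixel Dice ratio that counters class imbalance
(foreground clumps are sparse). The loss is negative by construction:
a perfect prediction attains exactly −1. `ε = 1e-7` defines the 0/0
case at `t = p = 0` as 0. The total objective is the final head's
hybrid loss plus the side loss; a `literal_eq6` flag instead multiplies
that sum by the depth `d` (a formulation that re-adds the same terms
once per row — equivalent up to learning-rate scaling, kept for
comparison only).

Training uses Adam at the default learning rate 5e-3 and batch size 32
(the package-wide defaults); the desk-scale experiments below override
the batch to 8. Masks are one-hot over C = 2 classes. `segment()`
reflect-pads inputs to a multiple of 2^d, thresholds the foreground
softmax probability strictly above `threshold` (default 0.5), and
crops back.

## Stage 2: label-contrastive classification

Each 8-connected component of the cleaned mask with area ≥ `min_area`
becomes a region of interest: the tile pixels under the component
(background zeroed), cropped to the bounding box and centred on a
square zero canvas; oversized components are downscaled preserving
aspect, never cropped. Mask cleanup is hole filling followed by a
morphological opening with a 3 px disk.

The classifier is a compact VGG-style encoder (stacked 3×3 conv +
ReLU + 2×2 max-pool stages, global average pooling) with two heads: a
linear classifier and a projection to a D-dimensional embedding,
L2-normalized. A *momentum encoder* — the same architecture whose
parameters follow `θ_k ← m θ_k + (1−m) θ_q` with m = 0.9 and receive no
gradients — encodes each batch into "key" embeddings pushed with their
labels into a FIFO memory bank (default capacity 4096). The
label-contrastive loss of a query `(q, y)` against bank keys
`(k_i, y_i)` is

    L_con = −log [ Σ_{i: y_i=y} exp(q·k_i / τ) / Σ_i exp(q·k_i / τ) ]

with τ = 0.07 and cosine similarity (unit embeddings, dot product).
It is zero iff every key shares the query's label, and equals
−log(n_pos/n) whenever all similarities tie. Positives are defined by
labels, not augmented views, so a second augmentation branch is
unnecessary: keys are momentum-encoder embeddings of the same images.
The training objective is `L_cla + β L_con` with β = 0.5 by default;
the contrastive term stays disabled until the bank holds at least one
key of every class, and a query with no positive key raises a distinct
error (a skip signal) rather than returning infinity. A sample whose
class is absent from the whole training set is rejected outright.

The classifier indicator convention deserves a note: one reading of
the cross-entropy indicator ("1 if classified correctly") would zero
the loss exactly on misclassified samples and provide no training
signal; the implemented loss is standard cross entropy with the
indicator selecting the true class.

Prediction ties break toward *malignant*: in screening, a false
negative (missed carcinoma) is the costly error.

## Evaluation

Dice = 2|T∩P|/(|T|+|P|), with the empty-vs-empty case defined as 1 (a
correctly predicted all-background tile is a perfect result).
Accuracy, sensitivity, precision and F1 come from the confusion counts;
ratios with zero denominators are reported as missing rather than
zero-substituted so cross-validation means are not biased. ROC points
come from a sweep over unique score thresholds (ties grouped) and AUC
is the trapezoidal area; the implementation delegates to scikit-learn
and is cross-checked in the tests against the Mann–Whitney U
equivalence. Cross-validation folds are split by source tile so no
tile's ROIs straddle a fold (slide- or patient-level grouping would be
the analogue on clinical data).

## Synthetic data: what it emulates and what it does not

`synthgen` renders, from a single seeded generator, tiles containing
0–10 non-overlapping "cell clumps": radially perturbed ellipses whose
boundary is a zero-mean harmonic series. Benign clumps use low
harmonics (2–5) at amplitude 4% of radius — smooth, neat edges;
malignant clumps use harmonics 2–9 at 25% — irregular, protruding
edges. This operationalizes the edge-based diagnostic criterion in a
measurable way: malignant clumps have strictly larger boundary
roughness (perimeter²/area), which the tests verify over ≥100 sampled
clumps. Interiors carry multiplicative smooth-noise texture
(chromatin-like, so segmentation is not a flat-colour threshold), and
the background holds small (≤6 px) discs emulating the single cells
and leukocytes a segmenter must reject (150 per megapixel by default).
Intensity maps through one of two 2-colour palettes (H&E-like,
Papanicolaou-like) by linear interpolation, so luminance ordering is
identical across styles and the mask is independent of the palette.
Clump placement is rejection sampling with a 4 px separation margin,
which guarantees the mask's connected components equal the clump list;
a spec too crowded to place raises after 500 attempts per clump.

What the generator does *not* emulate: nucleus-level structure,
three-dimensional clump appearance, stain variation within a protocol,
scanner artefacts, mucus, or touching/overlapping clumps. Passing the
synthetic experiments therefore shows that the architecture, losses
and pipeline plumbing work and that the two stages recover the
generative labels; it does not certify clinical performance on slides.

## Experiment sizes and defaults

All experiments are sized for a single CPU:

| experiment | conditions |
|---|---|
| segmentation recovery | 200 mixed-stain 128 px tiles (160 train / 40 held out), depth 2, 8 base channels, batch 8, 8 epochs, seed 0 |
| classification recovery | ~250 ROIs from 80 mixed-stain 192 px tiles (split by source tile), 64 px encoder input, 4 stages, embed dim 64, bank 512, batch 16, 30 epochs |
| β ablation | same data, 5 paired seeds, β ∈ {0, 0.5}, 12 epochs per arm, median held-out accuracy |

With these conditions the segmenter reaches held-out Dice ≈ 0.97 and
the classifier ≈ 0.95–0.99 held-out accuracy, and the β = 0.5 arm has
matched or beaten the β = 0 arm on every seed tried. The deeper
configurations (depth 4, ResNet-style backbone, VGG-16-sized encoder,
512 px canvases, bank 4096, batch 32) remain available through the
model constructors and configuration, but are not exercised by the
test suite.

## Numerical backend

The networks run on `cytoscreen.nn`, a reverse-mode autodiff engine on
numpy arrays written for this package (broadcasting arithmetic,
batched matmul, stride-1 same-padded convolution, 2×2 max pooling, 2×
nearest upsampling, concatenation, reductions, pointwise ops, Adam).
Convolution is computed as a sum of per-offset tensor contractions
rather than im2col, so no column matrix is materialized or retained;
backward recomputes the padded input, keeping peak memory under ~1 GB
for the experiment sizes above. Gradients are verified against central
finite differences in the test suite. All parameters are float32;
losses are computed in the graph with max-shifted softmax/logsumexp for
stability. Every source of randomness (generator, initialization,
shuffling) flows from explicit integer seeds; two runs with the same
seed are bit-identical.

## Known limitations

- The GAP branch of the deep-supervision path is omitted (see above).
- Overlapping clumps are out of scope (no watershed splitting); the
  generator never produces them.
- The literal `literal_eq2` / `literal_eq6` variants are fidelity
  switches, not recommended settings.
- Headline clinical metrics from slide datasets are not reproducible
  here: they require private data and GPU-scale backbones. The
  acceptance experiments are property-based at desk scale instead.
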