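# Methods

## Problem and approach

Tip-burn is a calcium-deficiency stress of lettuce grown in plant factories.
It appears as small (order 5×5 px at camera resolution) yellow-brown necrotic
spots at leaf tips, sparse and rare, on top-view images of dense canopies
holding ~1,000 plants.  Pixel-level annotation of such imagery is infeasible,
so the package performs *weakly-supervised* semantic segmentation: the only
supervision is an image-level class label (stressed / healthy patch).

The pipeline:

1. **Hard-stride splitting.**  A 352×576×3 tile is split into 64×64×3
   patches with stride 8 in both axes (`k = ⌊(dim − patch)/stride⌋ + 1`, no
   padding; 37×65 = 2,405 patches per tile).  The stride being much smaller
   than the patch makes neighbouring patches overlap heavily — interior
   pixels are covered by (64/8)² = 64 patches.
2. **Patch classification.**  Each patch is resized to the classifier's
   input side ℓ and scored by a softmax classifier; the positive-class
   probability of patch (r, c) becomes entry (r, c) of the probability
   configuration (CoP).  The same classifier serves whole images and
   resized crops: canopy crops look like canopies (*decomposition
   principle*).
3. **Reconstructed attention map (RAM).**  Every patch pixel deposits its
   patch's probability at its source location `(i + r·s_x, j + c·s_y)`; the
   accumulated map divided by the per-pixel overlap count gives the averaged
   map RAM\*.  With patch 64/stride 8, RAM\* is piecewise constant on 8×8
   blocks — its "probability resolution".
4. **Node re-split.**  Image and RAM\* are re-split into non-overlapping
   8×8 nodes (44×72 = 3,168 nodes per tile).  Node features are the raw
   flattened 8×8×3 blocks (k = 192); node probabilities are block means of
   RAM\*.
5. **Graph refinement.**  Per image, nodes are joined by an edge when the
   Jensen-Shannon divergence between their 64-bin RGB+HSV colour histograms
   falls below β; a 3-layer first-order spectral GCN
   (`H(t+1) = ReLU(Â H(t) W(t))`, `Â = D̃^{-1/2}(Adj + I)D̃^{-1/2}`, softmax
   head) is trained transductively on pseudo-labels obtained by
   thresholding the node probabilities, with cross-entropy over all nodes
   and Adam.  The refined node probability is the positive column of Z.
6. **Reconstruction and attribution.**  Node masks are expanded to pixels,
   tiles are placed back at their recorded offsets, and each connected
   lesion component is attributed to the tray/cell containing its centroid.

Evaluation uses patch-level ("super-pixel") metrics on the node grid:
`DSC = 2|X∩Y|/(|X|+|Y|)` and `IoU = |X∩Y|/|X∪Y|`, identical to pixel
metrics because nodes are uniform blocks.  Both are defined as 1 when both
sets are empty.

## Why the thresholds sit where they do

The averaged attention map of a point lesion does not fall off sharply: a
pixel one node (8 px) away from a lesion is still covered by 49 of its 64
covering patches containing the lesion, so RAM\* ≈ 0.77 there, and a cut at
0.5 selects a ~7×7-node halo around every lesion.  The reference results
for plain RAM thresholding are far too good for that regime, implying an
operating point where the thresholded map is tight.  The baseline/pseudo-
label cut therefore defaults to **0.9** (> 49/64), which keeps labels
within one node of the lesion; the cut on *refined* probabilities stays at
0.5, where the GCN output is well saturated.  Ground-truth nodes for
evaluation are blocks with ≥ 1/8 lesion coverage, emulating a human
selecting visibly stressed super-pixels (a single stressed pixel does not
make a block selectable).  All three are configurable.

## The similarity graph and β

β is a per-dataset quantity.  The reference value 0.005 suits smooth
close-up foliage where same-material histograms nearly coincide; on the
synthetic texture (and plausibly on other cameras) pixel-level variation
alone puts same-material JSD near 0.03–0.1, and a fixed 0.005 leaves the
graph edge-free — refinement then degenerates to a per-node classifier
that leaves scattered colour-lookalike false positives.  `beta="auto"`
calibrates the threshold label-free from the JSD distribution itself: β is
set so the median node has ~5 neighbours (the usual sparse kNN-similarity-
graph regime of graph-based semi-supervised learning).  Edges let the
propagation pull mislabelled or lookalike nodes toward the label majority
of their material, which is the refinement mechanism the method is built
around.  The package default remains the reference 0.005; the synthetic
harness overrides it with `"auto"`.

## Training configurations

**Patch classifier.**  The production backbone is a fine-tuned pretrained
CNN behind a pluggable contract (`predict_proba` over resized patches); it
is consumed as an opaque asset and never downloaded here.  The desk-scale
implementation is `SmallPatchCNN`: a shared 8×8/stride-4 convolution bank
(32 channels), ReLU, global max pooling, a 32-unit dense layer and a
softmax head, written in numpy.  Global max pooling provides the position
invariance a lesion detector needs ("does any window look discoloured");
a dense net on raw pixels is provably at chance here.  Training:
categorical cross-entropy, Adam, early stopping with patience 4 and
min-delta 0.001, plateau LR reduction ×0.2 down to 0.001.  The initial
learning rate defaults to 0.01: the fine-tuning recipe's 0.1 presumes a
pretrained backbone and diverges on a from-scratch network.  Input side ℓ
defaults to the native 64 (ℓ is dataset/backbone-dependent by design;
downsampling to 32 erases 4-px lesions).

**GCN.**  Hidden widths 64/32, output 2, Adam at 0.01, weights
Glorot-initialised, no bias terms (the propagation rule has none; note
this makes the network positively homogeneous — classes must differ in
feature *direction*, which colour classes do).  Training is full-batch, so
one epoch is one gradient step; the majority class is fit within ~100
steps while the <1% positive minority needs ~1,000–2,000, with loss
improving by only ~3×10⁻⁵ per step in between.  Early stopping is
therefore sized in steps: max 2,000 steps, patience 500, min-delta 10⁻⁴,
best-loss weights restored.  Histogram smoothing adds 10⁻¹² to both
histograms before the KL terms (natural log throughout); JSD is computed
via `JSD = H(m) − (H(p)+H(q))/2` in chunks for the full 3,168² matrix.

**Leaf preprocessing.**  The foreground/background MLP (192 inputs, hidden
64/32) is trained per dataset on pooled corner (background) and centre
(foreground) 8×8 patches; the mask keeps the largest connected component
of the 8×8-block classification before bounding-box cropping, and
background pixels are set to exactly (0,0,0).

**Ablation harness.**  Four variants: thresholded RAM baseline, 2-layer
GCN, 3-layer GCN, and "doubled nodes" — the positive pseudo-label set
grown to twice its size by admitting the next-most-probable nodes (the
reference procedure is not operationally defined; this interpretation is
configurable).  With tight pseudo-labels the doubled set can add genuine
lesion nodes on some images, so the degradation the reference reports is
a tendency, not an invariant, of this harness.

## Synthetic data

The real imagery (proprietary plant-factory tables; single-leaf datasets)
is replaced by generators with exact ground truth:

* **Canopy** (352×576 default): overlapping randomized green ellipses
  ("leaves", hue 0.22–0.38) with mild shading noise (σ = 0.02) and a final
  σ = 1 Gaussian blur; lesions are non-overlapping yellow-brown disks
  (hue 0.07–0.13), count Poisson(3), radius 2–6 px (diameter 4–12 px),
  placed fully inside the image; the mask is exactly the rendered disks.
* **Leaf** (256×256): one green ellipse kept ≥ 16 px clear of the corners
  on a near-uniform dull background, with optional brown spots inside it.
* **Patch sets**: 64×64 crops of the same texture, lesion class containing
  exactly one lesion at a uniform random position; classes are separable
  by construction.

What the generator does *not* emulate: real leaf morphology and specular
shading, lesion textures (rendered spots are flat discolourations),
camera noise and vignetting, the full 4,640×6,960 table resolution, and
class imbalance at training time (patch sets are balanced).  A green test
therefore establishes that the pipeline machinery recovers small rare
discoloured regions under the stated geometry — not field performance on
plant-factory imagery.

## Numerical and degenerate-input choices

* Grid arithmetic uses the floor convention; trailing pixels not covered
  by any patch are excluded from the map (overlap count 0) and masked out.
  The canonical geometries tile exactly, so nothing is lost there.
* Overlap-average division guards count-0 pixels (they stay 0).
* Node indexing is column-major (`i = c·w + r`, w grid rows), matching the
  feature-matrix convention used throughout.
* Single-class pseudo-labels skip refinement with a warning and pass the
  thresholded baseline through unchanged; `max_epochs = 0` is an explicit
  passthrough contract.
* JSD inputs are validated to sum to 1 (1e-6); its range [0, ln 2] is
  exact up to the ε-smoothing.
* All randomness flows through `numpy.random.Generator` seeds carried in
  the configs; fixed seeds reproduce every artifact bit-exactly.

## Known limitations

* The bias-free GCN cannot separate classes whose features differ only by
  a positive scale factor; colour classes differ in direction, but
  grey-level-only contrasts would be invisible to it.
* DSC on canopies with a single small lesion is quantized (2–4 ground-truth
  nodes), so per-image scores are volatile even when the segmentation is
  visually correct; harness means are taken over several canopies.
* Lesions close to the image border sit in the low-overlap band of the
  attention map, where averaging cannot suppress the halo; the graph
  refinement, not the threshold, handles those.
* The ~25 s per-image refinement cost (3,168² JSD matrix + 2,000 GCN
  steps) is the price of the transductive design; batching across images
  keeps graphs block-diagonal and is embarrassingly parallel.
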