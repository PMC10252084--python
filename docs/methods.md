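# Methods

This note documents the models, conventions, calibrations and
limitations of the `sheepface` package, in the order a reader needs them
to interpret the numbers the code produces.

## The detection model

The baseline is the v6.1 layout of the YOLOv5s family at width multiple
0.5 and depth multiple 0.33:

| stage | layer | output channels (stride) |
|---|---|---|
| P1 | 6×6/2 CBS stem | 32 (2) |
| P2–P5 | 3×3/2 CBS + C3×{1,2,3,1} | 64, 128, 256, 512 (4–32) |
| — | SPPF (three chained 5×5 stride-1 max pools) | 512 |
| neck | FPN+PAN: 1×1 CBS, 2× nearest upsample, concat, C3 (no shortcut), two 3×3/2 CBS | 128/256/512 |
| head | 1×1 conv with bias per scale | 3·(nc+5) |

CBS is convolution (no bias) + batch norm + SiLU. All convolutions that
feed a batch norm are unbiased. Head biases are initialised to the usual
prior-probability values (objectness ≈ 8 objects per 640² image, classes
≈ 0.6/(nc−1)).

Variant switches (interface-preserving — every variant accepts the same
inputs and emits the same output shapes):

* **ghost_neck / ghost_backbone** — every CBS in the respective part
  becomes a GhostConv (primary convolution to n/2 channels + cheap 5×5
  depthwise ops, ratio s=2) and every C3 a C3Ghost whose repeated unit
  is the ghost bottleneck (two stacked 1×1 ghost modules, residual
  identity at stride 1). The stem and SPPF are retained.
* **shufflenet_backbone** — the four stride-2 CBS downsamples become
  ShuffleNetv2 downsampling units (left branch: 3×3 depthwise stride 2 +
  1×1; right branch: 1×1, 3×3 depthwise stride 2, 1×1; concat + channel
  shuffle with two groups). Batch norm follows every convolution; ReLU
  follows the 1×1 convolutions only, per the original design. The stem
  and the C3 stacks are retained — this mapping reproduces the published
  parameter delta (−1,294,080) exactly.
* **attention ∈ {ca, se, eca, cbam}** — one gate inserted on the
  512-channel map immediately in front of SPPF; nowhere else.

These choices reproduce the published parameter budgets exactly:
7,189,540 (baseline, nc=63), 5,786,004 (+ghost neck), 5,895,460
(+ShuffleNetv2), 3,851,756 (ghost backbone+neck), 5,255,292 (ghost
backbone), 4,785,860 (full lightweight configuration).

## The calibrated coordinate-attention block

Coordinate attention pools the C×H×W input along each spatial direction
(z^h per row, z^w per column), passes the concatenated strips through a
shared 1×1 bottleneck (batch norm + hard-swish), splits, and maps each
strip back to C channels through a 1×1 convolution and a sigmoid; the
two directional gates reweight the input elementwise.

The published parameter budget of the attention-augmented variants
implies the inserted block adds exactly 293,936 parameters at C=512. No
textbook coordinate-attention block matches that number at any integer
bottleneck width (we searched widths 4–768 with every bias/batch-norm
combination and kernel sizes 1–7). The source describes its attention
block as providing *both* channel and spatial attention, so the package
calibrates a dual-gate block that matches the budget exactly:

* directional branch: conv1 512→184 (bias, BN, hard-swish); gate convs
  184→512 with BN and no bias — 285,224 parameters;
* channel branch: squeeze-excitation with bottleneck width 8 (biased
  1×1 convs, no BN) — 8,712 parameters.

This structure is an inference, not something the source states; it is
the package's documented calibration (the standard reduction-32 block
remains available via `CoordAtt(c)` / `make_attention("ca", c,
calibrated=False)`).

## FLOPs reporting convention

`count_flops` reports

```
GFLOPs = (2 × conv MACs + 4 × batch-normalised output elements) / 1e9
```

at the stated square input, with the detection head evaluated at the
reference 80-class width. This is the convention under which the
published model summaries of this detector family are produced
(parameter counts, by contrast, are always for the model as built —
nc=63 here). Under it the published 16.5 (baseline), 14.0 (ghost neck),
14.1 (ShuffleNetv2), 11.3 (ghost backbone) and 11.6 (ghost neck +
ShuffleNetv2) all reproduce at one decimal.

One published FLOPs value does not reproduce: the attention-augmented
rows print a +0.7 G step. A convolutional block with 293,936 parameters
acting on a 20×20 map cannot exceed 2·400·293,936 ≈ 0.24 GFLOPs under
any 2×MACs convention (MACs = parameters × positions bounds any
weight-shared operation), and the strip convolutions of coordinate
attention actually add ≈ 0.015 G. The profiler therefore reports
≈ 11.6 G for the full lightweight configuration where the source prints
12.3 G; the printed parameter and FLOPs columns for the attention rows
are mutually inconsistent, and this package sides with the parameter
column (which is internally consistent across all printed rows and
deltas).

## Loss, assignment and training loop

The objective is the standard composite for this detector family:
box term 1 − CIoU, objectness BCE with IoU-valued targets, class BCE;
gains 0.05/1.0/0.5, per-scale objectness balance 4.0/1.0/0.4, and the
total scaled by the batch size. Targets are matched to every anchor
within a 4× width/height ratio and routed to the cell containing the
center plus its two nearest neighbours (offset 0.5). Box decode:
center (2σ(t)−0.5+cell)·stride, size (2σ(t))²·anchor. Anchors are
stored in a 640-pixel reference frame and rescaled to the actual input
so training and decoding agree at any resolution.

Optimisation: SGD, momentum 0.937, weight decay 5·10⁻⁴ on convolution
kernels only, linear warmup (2 epochs) into a cosine decay to 10% of
the peak rate. Default hyper-parameters follow the source's training
setup (initial rate 0.001, batch 16, 50 epochs); the desk-scale runs in
this repository use their own documented settings (below). Mosaic
stitching is applied to half the training samples and never at
evaluation. Exponential moving averages and multi-process data loading
are deliberately out of scope.

Cross-validation in the source is unspecified beyond "averaging multiple
sets"; the package models it as repeated seeded runs.

## The synthetic fixture generator

Each identity class is a procedurally drawn face: elliptical head, two
ear triangles, eyes, muzzle, plus a seed-stable identity pattern —
count, position and colour of dark spots placed around the eyes, ears,
cheeks and mouth, together with a coat tint and ear/muzzle darkness.
Per-image jitter covers pose (position, scale), brightness (0.62–1.32),
background colour and clutter, and sensor noise. Ground-truth face boxes
are computed from the drawn geometry, not re-estimated.

What it emulates: one face per image with identity-bearing local
markings, variable illumination and scale — enough to exercise every
stage of the pipeline (labels, splits, augmentation, anchors, loss,
NMS, mAP). What it does not emulate: occlusion, pose out of plane,
multiple animals per frame, motion blur, and the intra-class variability
of real fleece and lighting. A pass on this fixture therefore
demonstrates that the architecture and pipeline can learn and localise
identity-bearing patterns at desk scale; it says nothing quantitative
about accuracy on real sheep imagery (the source's accuracy figures are
measured on a non-public dataset and are out of scope here).

## Desk-scale benchmark conditions

The training benchmark fixes: 5 identities × 20 images (320² source
images, 8-1-1 split), 96-pixel input, `lsr_yolo` preset, 40 epochs,
initial rate 0.01, batch 16, mosaic on, adaptive anchors on, seed 0.
Adaptive anchor estimation (IoU k-means + mutation over the training
boxes — the input-stage step the source's own pipeline includes) is
part of the recipe because the fixture's ~50-pixel faces fall between
the stock anchor scales at a 96-pixel input. Under these conditions the
detector reaches mAP@0.5 = 1.0 on the held-out splits in about three
minutes on one CPU core. The acceptance threshold for this stochastic
benchmark is mAP@0.5 ≥ 0.9.

## Numerical choices and degenerate inputs

* float32 throughout; batch-norm eps 10⁻³, momentum 0.03.
* AP integrates the monotone precision envelope with the trapezoidal
  rule; ties in confidence are broken by stable sort order.
* precision/recall at 0/0 are defined as 0; classes absent from the
  ground truth are skipped by mAP.
* k-means anchor estimation handles an all-identical box set by
  returning that size for every anchor; mutation factors are clipped to
  [0.5, 2] and accepted only when the mean best-anchor IoU improves.
* Rotation and letterboxing fill with gray 114; boxes rotated or
  clipped out of frame are dropped with a logged count.
* The split apportions per-class val/test quotas by largest remainder so
  the global 8-1-1 counts are exact and every class keeps a training
  item.

## Known limitations

* No GPU, mixed precision, EMA, or mobile export; the engine is tuned
  for desk-scale problem sizes (≤ 128-pixel inputs, ≤ a few hundred
  images).
* FLOPs for the attention-augmented rows differ from the source for the
  documented reason above.
* The calibrated attention width is an inference from printed budgets;
  treat the block's internals as a reconstruction, not ground truth.
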