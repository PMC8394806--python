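# Methods

## The measurement

Adenoid hypertrophy (AH) screening on a lateral cephalogram uses Fujioka's
adenoid–nasopharyngeal ratio. Four landmarks are involved: basion (Ba) and
articulare (Ar), whose chord stands in for the tangent to the occipital
slope; A′, the point of maximal convexity of the adenoid shadow; and the
posterior nasal spine (PNS). The adenoid depth is

    A = d(A′, line(Ba, Ar))

the perpendicular distance of A′ to the skull-base line. The original
description of the nasopharyngeal span N is given graphically rather than as
an explicit formula, so this package fixes a convention that uses only the
four annotated landmarks:

    N = ‖PNS − F‖,  F = perpendicular foot of A′ on line(Ba, Ar)

i.e. the distance from the palate edge to the point where the adenoid
projects onto the skull-base line. A and N scale together under similarity
transforms, so the ratio A/N is invariant under rotation, translation,
scaling and reflection of the film — a property the test suite checks
explicitly. A ratio strictly greater than 0.6 is read as suspected AH; the
boundary value 0.6 itself is classified normal. Degenerate inputs (Ba = Ar,
or PNS coinciding with F) raise typed errors rather than returning sentinel
values.

## The detector

`HeadNet` is a stacked-hourglass keypoint network. A stem (7×7/stride-2
convolution to 64 channels, 1×1 expansion to the working width, max-pooling
down to the heatmap resolution) feeds `n_stacks` hourglass encoder–decoders
built from bottleneck residual modules (1×1 reduce → 3×3 → 1×1 expand, each
convolution followed by ReLU, identity shortcut). Attention residual modules
— the same bottleneck gated first by a channel gate (global average pool →
1×1 → ReLU → 1×1 → sigmoid) and then a spatial gate (per-pixel channel
mean/max → 7×7 convolution → sigmoid) — sit at the entry and exit of each
stack; hourglass interiors use plain residual modules. At full scale the
width is 256 with a 128-channel bottleneck and a 16-channel channel-attention
bottleneck; reduced models scale the width and keep the ratios.

Each stack ends in a 1×1 head with one heatmap per landmark. Heatmaps are
converted to coordinates by integral regression: raw scores are softmax-
normalized over all pixels (temperature 1, no preliminary activation) and
the expectation of pixel-center coordinates is returned. Outputs are convex
combinations of grid positions, hence always strictly inside the image —
no clamping. Intermediate stacks are merged back into the feature stream
(1×1 projections of features and heatmaps) so every stack can be supervised.

Design points that the architecture description left open, fixed here:
two stacks as the minimal stacked configuration at full scale; stem
downsampling 256→64 via the stride-2 conv plus one max-pool (64×64 is the
standard hourglass working resolution); attention modules at stack entry and
exit only. The head convolutions are initialized at 5% of the He scale:
with full-scale He weights the random initial heatmaps already saturate the
softmax and integral regression starts at an arbitrary saturated pixel with
vanishing gradients, whereas near-uniform initial heatmaps start the
coordinate estimate at the grid center.

## Losses

The base loss is the mean absolute (L1) difference between predicted and
true coordinates, averaged over the 8 components; it is computed in
heatmap-grid units inside the loop and reported in input pixels (conversion
factor `input_size / heatmap_size`). Two auxiliary geometry priors penalize
exactly the errors that corrupt the A/N measurement:

* translation loss `(Da + Db)/2`, where `Da`/`Db` are the distances of the
  predicted Ar/Ba to the ground-truth Ar–Ba line. Zero for any prediction on
  the true line regardless of along-line displacement — it is a
  line-consistency prior, not a duplicate of the L1 term.
* rotation loss: the unsigned acute angle between predicted and true Ar–Ba
  directions, computed as `atan2(|u×v|, |u·v|)` (order-independent, stable
  near parallel).

Both default to weight 0.1, chosen so the priors stay auxiliary (≈10% of
the base-loss magnitude at convergence on synthetic data); both are exposed
in config, and setting them to zero recovers the plain baseline arm of the
ablation. With intermediate supervision the composite loss is summed over
all stacks.

Optimization is SGD with batch 10, momentum 0.9 and weight decay 2×10⁻⁵.
The schedule warms up linearly from a tenth of the base rate to the base
rate of 0.001 over five epochs (the warm-up shape is a convention; any
positive ramp reaching 0.001 satisfies the protocol), then multiplies by
0.9 every five epochs. The annealing factor is likewise a package default,
not a quoted value. Weights are initialized He-style from the run seed;
training is bit-reproducible given the seed, and the checkpoint with the
lowest validation A/N error is retained.

The network, the differentiable operations (convolution as an im2col BLAS
product, pooling, upsampling, the spatial soft-argmax) and the optimizer are
implemented in this package as a small reverse-mode autodiff engine on numpy
arrays (`adenoceph.nn`), dtype-preserving so gradient checks run in float64.

## Synthetic data

Clinical cephalograms cannot be redistributed, so `adenoceph.synth` renders
images that preserve the geometric structure of the task: a bright clivus
ridge whose endpoints are Ba and Ar (with distinct knobs at the two ends), a
tapering hard-palate wedge whose posterior tip is PNS, and a soft elliptical
adenoid pad whose extreme point along the line normal is exactly A′, plus
Gaussian blur and pixel noise. The landmark geometry is sampled first and
the requested A/N ratio is imposed by construction (A′ = F + ratio·N·n̂), so
ground truth is exact; rendering never moves it. Severity strata mirror a
651:197:53 normal:moderate:severe case mix, with normal ratios drawn from
[0.25, 0.58] and hypertrophic from [0.62, 0.95]; the gap around 0.6 keeps
labels unambiguous under small landmark noise and is configurable for
borderline studies. All landmarks stay a margin (image_size/8 by default on
small canvases, 32 px at 256) from the border so augmentation can keep the
region of interest inside the image.

What the generator does **not** emulate: cervical vertebrae, dentition,
soft-tissue profile, exposure variation, or the ambiguity of the adenoid
contour on real film — the main reported source of A′ localization error.
Passing tests on synthetic data therefore demonstrate that the pipeline is
correctly wired and can recover geometry it has seen, not clinical-grade
performance; synthetic results are systematically better than what the same
architecture achieves on real cephalograms.

## Augmentation

Each training image yields 17 variants: the original, shifts of 10 px in
the four axial directions and (±20, ±20) px diagonally ("20 px diagonal" is
interpreted as 20 px along each axis), and 8 rotations about the image
center. The rotation count is not stated explicitly anywhere; 8 is forced by
the dataset arithmetic (581 × 17 = 9877 with 1 original + 8 shifts + k
rotations), and the angles ±5°, ±10°, ±15°, ±20° are the even spacing of
[−20°, 20°] with zero excluded. Landmarks are transformed with the exact
continuous affine map about ((W−1)/2, (H−1)/2); images are warped bilinearly
with zero fill. A variant that would push a landmark outside the image has
its magnitude deterministically halved (at most 10 times) until valid, so
the 17× count law is exact rather than approximate.

## Evaluation

* Localization: mean Euclidean error per keypoint and averaged, in input
  pixels.
* AP/AR: the metric names come without a matching rule; since the detector
  emits exactly one prediction per keypoint (no confidence ranking, making
  score-ranked AP degenerate), a PCK-style rule is used — correct at
  threshold t iff the error is ≤ t px, averaged over thresholds 1..10 px
  (configurable). Precision equals recall under this rule.
* A/N ratio error: mean |predicted − true| ratio, with degenerate samples
  excluded and counted.
* Diagnostics: confusion matrix with hypertrophic positive; sensitivity,
  specificity, accuracy, precision, F1 with Wilson score 95% CIs
  (statsmodels); likelihood ratios by the standard formulas
  LR+ = sens/(1−spec), LR− = (1−sens)/spec. Note that for an operating
  point of sensitivity 0.906 and specificity 0.938 these give 14.6 and
  0.100; figures of 10 and 0.067 sometimes quoted for such a point
  correspond to the formulas with sensitivity and specificity exchanged.
  The standard definitions are used and not adjusted.
* ROC/AUC: the predicted A/N ratio is the continuous diagnostic score
  (scikit-learn curve/AUC; the AUC equals the Mann–Whitney statistic with
  ties at 1/2, verified against an all-pairs oracle). The 95% CI is a
  2000-replicate percentile bootstrap stratified by class, seeded.

## Desk-scale study sizes

The standard demonstration (`adenoceph.experiments.run_reduced_study`, also
the basis of `scripts/acceptance.py`) uses 64 px images, heatmap 16, a
single stack of width 64 and hourglass depth 2, a 300/60/150
train/validation/test cohort, 17× augmentation with displacements scaled by
the 256→64 factor (3 px axial, 5 px diagonal, rotations unchanged), and 6
epochs of SGD with a 2-epoch warm-up to a base rate of 0.02. The higher
rate is a property of the reduced problem: at this scale the full-protocol
0.001 converges far more slowly per unit work, while 0.02 reaches
sub-pixel validation localization within a few epochs. These sizes were
chosen so the whole study trains in minutes on a single CPU core while
still exercising every stage of the pipeline; the ablation harness runs the
same study for the four arms (± attention, ± geometry-prior losses).

## Known limitations

* Synthetic-only validation; no claim of clinical performance transfers.
* The N-segment convention above is a documented choice, not a canonical
  definition; alternative conventions shift the absolute ratio slightly but
  preserve its invariances.
* The engine is CPU-only and optimized for small models; full-scale
  (256 px, width 256, two stacks, 200 epochs) training is expressible but
  slow in this implementation.
* Intensity augmentation, elastic deformation and detection-style OKS
  metrics are deliberately out of scope.
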