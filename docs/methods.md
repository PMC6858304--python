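# Methods

This note describes the models and procedures netquant implements, the
assumptions behind them, the synthetic data they are validated on, and the
numerical choices a maintainer would want spelled out.

## The quantitation problem

NETosis — cell death by Neutrophil Extracellular Traps — begins with
chromatin decondensation: the resting neutrophil's multilobulated, bright
nucleus swells into a sphere with a diffuse stain before the DNA is
extruded. Counting the fraction of NETotic nuclei in a SYTOX-stained
well therefore reduces to classifying nuclear morphologies in 16-bit
wide-field images and tallying them. Necrotic death must not be confused
with NETosis; its hallmark is the opposite chromatin change —
condensation into bright clumps inside a swollen, dim body.

netquant implements two counting routes over a shared 3-class taxonomy
(0 = background/other, 1 = non-NETotic, 2 = NETotic; necrotic nuclei carry
label 3 in annotation files):

* **Pixel-level (PL)**: a 32x32 patch classifier is slid at stride 1 over
  the field, producing an (H-32) x (W-32) x 3 class-score map (a 512x672
  field maps to 480x640x3 — the scan covers offsets 0..H-33); a second,
  small network regresses the two per-field counts from that map.
* **Object-level (OL)**: classical morphology (Isodata threshold, repeated
  3x3 opening, 8-connected components) detects objects; a patch around each
  object centre is classified; per-object labels are tallied. This route
  also yields the per-phenotype centre lists that the spatial statistics
  consume.

## Network architectures and training

All four networks are built and trained by the package's own numpy CNN
engine (`netquant.nn`): explicit forward/backward layers (valid stride-1
convolution via kernel-offset GEMMs, 2x2 max/average pooling, inverted
dropout, dense layers, ReLU), minibatch SGD with momentum 0.9, learning
rate 1e-3, and per-update decay eta_t = eta0/(1 + 1e-7 t). The engine is
deliberately small and fully deterministic under a seed — weight init,
shuffling and dropout all derive from one generator — which is also what
makes the guided backward passes for the saliency maps a one-flag variant
of ordinary backprop rather than a separate code path.

* `pl_stage1` (32x32 -> 3): four 3x3 convolutions of 64 filters, 2x2
  max-pool and 25% dropout between the second and third, a 256-unit dense
  layer, 3-way softmax. Cross-entropy loss, batch 32.
* `pl_stage2_counter` (score map -> 2 counts): two 3x3 convolutions of 32
  filters with 2x2 average pooling between and 2x2 max pooling after,
  256 dense units, and a rectified 2-unit head (counts are non-negative by
  construction). Mean-absolute-error loss, 30 epochs by default. The head
  activation is rectified linear like every other unit; a linear head is a
  one-line change if negative intermediate estimates are ever wanted.
* `phenotype` (100x100 -> 2): nine 3x3 convolutions of 64 filters with 2x2
  max-pool + 25% dropout after every third, 256 dense units, 2-way softmax;
  decision threshold 50% on the class-1 probability (equivalent to argmax
  for a binary softmax). Trained up to 100 epochs.
* `ol_classifier`: a compact densely connected backbone (stem convolution,
  two dense blocks whose 3x3 convolutions see the concatenation of all
  earlier block features, max-pool transitions), global average pooling and
  a 3-way head. Global pooling makes it input-size agnostic; the canonical
  object patch is 112x112. Weights are randomly initialised under the seed
  — the package ships no pretrained weights, and the backbone is sized so
  that random init trains fine on the synthetic patches.

Every builder takes a `width` argument that scales the convolutional
filter counts without touching the topology. The full widths (64/32/64)
are the defaults; the desk-scale profiles used in the test-suite and in
`scripts/acceptance.py` are width 8-16 for field-scale experiments and the
phenotype net, because stride-1 map generation and 100x100 forward passes
dominate CPU time while classification accuracy at difficulty 0 saturates
long before the full width is needed. Epoch counts in those runs (4-16)
are likewise chosen at the point where the validation loss has plateaued
on this data; the configured maxima (30/100) remain the defaults.

Optimiser readings where the source description is ambiguous: "decay" is
implemented as per-update learning-rate decay (a weight-decay reading
would be a one-line alternative); the object-level "reduce the learning
rate every 10 iterations" schedule is implemented per epoch
(`TrainConfig.lr_step`), with early stopping once validation loss rises
while training loss falls (`patience` configurable).

## Synthetic data

Real annotated neutrophil images at the scale needed for training are not
redistributable, so `netquant.synth` generates fields and patches with
exact ground truth. Every nucleus is a sum of anisotropic 2-D Gaussian
components:

* non-NETotic — 2-4 elliptical lobes (sigma ~0.4r x 0.3r) arranged on a
  ring at 0.62r, peak 26-34 kcounts, light blur (0.6-1.0 px);
* NETotic — one large component (sigma ~0.52r), radius 10.5-13 px, heavy
  decondensation blur (2.6-3.4 px);
* necrotic — a dim swollen body (~10% of peak) plus 3-5 bright compact
  clumps (sigma 1.7-2.4 px, peak 42-52 kcounts, frequently saturating the
  16-bit range as condensed chromatin does).

The decondensation blur is folded into each component's covariance
analytically with conserved integrated intensity, so diffuse nuclei are
dimmer per pixel exactly as a conserved amount of stained chromatin would
be. Images are completed by Poisson shot noise on the signal plus a
Gaussian read-noise background (offset 200, sd 60 counts) and quantised to
uint16. Identical specs (including seed) render bit-identical images.

A single `difficulty` dial in [0, 1] linearly interpolates every class's
parameter range toward a common overlapping regime (radii converge, peaks
converge, lobes merge via a shrinking lobe offset with amplitude
renormalisation). At difficulty 0 the three classes are linearly separable
on the (area, solidity, peak intensity) features the rule-based baseline
measures — this is a designed, tested contract of the generator, giving a
regime where classifier ceilings are known. At difficulty 1 the same
features no longer support linear separation.

NETotic nuclei optionally carry a treatment subtype: PMA-like (ROS
pathway) nuclei are rounder and smooth; A23187-like (calcium-ionophore /
PAD4 pathway) nuclei are more eccentric and carry faint residual-chromatin
speckles. `subtype_separation` scales both offsets: at 0 the two subtype
distributions coincide (a classifier can only reach chance), at 1 they are
cleanly separable. This dial brackets — it does not reproduce — the
intermediate accuracy regime reported for real PMA vs A23187 nuclei.

Spatial arrangements: `hardcore_poisson` places centres by sequential
inhibition (no two closer than `hardcore_distance`; distance 0 recovers
complete spatial randomness), emulating dispersed NETosis;
`thomas_cluster` scatters centres around Poisson parents with
`cluster_sigma`, emulating clustered NETosis, conditioned on the exact
requested count. Dose series draw per-well NETotic counts binomially
around a 4PL mean plus Gaussian plate noise.

What the generator does *not* emulate: optical PSF and vignetting,
stitching seams, uneven illumination, debris and spread NETs (labels 4/5
are part of the vocabulary but never generated), multi-channel
immunofluorescence, and human annotation error. Passing tests therefore
demonstrate the pipeline's correctness and its behaviour under controlled
morphology overlap — not performance on real micrographs.

## Spatial statistics

The clustering statistic is the average nearest neighbor distance (ANND):
the mean over points of the Euclidean distance to the closest other point
(undefined below 2 points; neighbor search via scikit-learn). Under
complete spatial randomness at intensity lambda its expectation is
1/(2 sqrt(lambda)) (Clark-Evans). No edge correction is applied; all tiles
in a comparison share one size, so the bias cancels between conditions.

Because ANND depends on the number of cells in a tile, two conditions are
compared only after cell-count marginal matching, in three stages: (1) the
larger record set is culled uniformly at random with keep probability
equal to the size ratio; (2) both sets are truncated above the smaller of
the two count maxima; (3) for each record of the un-culled (reference)
set, the closest-count record of the other set is drawn (ties uniform at
random, with replacement). The reference and resampled ANND samples are
then compared with a two-sample Kolmogorov-Smirnov test — D is the
empirical-CDF sup-distance; the default p-value uses the asymptotic
Kolmogorov distribution at effective size n1 n2/(n1+n2), with a
permutation p-value available for small samples — and the whole
match-and-test cycle is repeated (default 10 times) with fresh randomness,
reporting all replicate p-values and their arithmetic mean.

A calibration caveat, quantified in the test-suite: the matching stage
makes the null distribution of p slightly non-uniform (stratification by
count is conservative, with-replacement duplication anticonservative).
The null false-alarm rate at the 5% level stays near nominal, but exact
p-value uniformity should not be assumed.

Tiling follows a rows x cols grid with floor-sized tiles and the remainder
absorbed by the last row/column; tiles with fewer than 20 NETotic cells
are discarded before ANND analysis (a tile at exactly 20 is retained).

## Dose-response analysis

Responses (% NETotic nuclei) are normalised affinely so the smallest
concentration-group mean maps to 0 and the largest to 100, then fitted
with the 4-parameter logistic
y = bottom + (top-bottom)/(1 + 10^((log10 EC50 - log10 x) h)) by
least squares in log10-concentration space. The Hill slope is free
(initialised at 1), EC50 is initialised at the median log-concentration
with a 3-point multi-start across a third of the concentration span to
dodge local minima; `constrain=True` fixes the asymptotes at 0/100. The
EC50 confidence interval comes from the asymptotic covariance on the
log10 EC50 scale (t critical value at n-p degrees of freedom); the
pointwise 95% band uses the delta method on the fitted curve. Note the
4PL symmetry (bottom, top, h) <-> (top, bottom, -h): fits may legitimately
return either parameterisation of the same curve.

## Rule-based baseline

The classical comparison pipeline: Isodata intermeans thresholding
(iterate t <- (mean below + mean above)/2 from the global mean to a step
under 0.5 grey levels), 8-connected components, removal of objects under
100 px or touching the border, then a threshold on a shape statistic
splitting "large diffuse" from "small compact" objects. The historical
threshold constant 5.677 is said to apply to solidity (area/convex area),
which cannot exceed 1 — so the statistic is pluggable (`solidity`,
`1/solidity`, `area/solidity` = convex area, `perimeter^2/area`, `area`)
with 5.677 kept as the default constant for the historical pairing and a
convex-area threshold of 200 px as the package's own calibration for the
synthetic stain at field scale. Blank fields are guarded: if the
above/below-threshold means are separated by less than 5 background
standard deviations, no objects are reported (an intermeans threshold on
pure noise otherwise lights up half the image).

## Saliency maps

Both methods emit non-negative maps at input resolution, computed from the
trained network's own backward graph:

* **Guided backpropagation**: the gradient of the target class logit with
  respect to the input, with every ReLU's backward pass additionally
  zeroing negative upstream gradients; residual negative input-gradients
  are clipped at the end.
* **Guided Grad-CAM**: the last convolutional layer's rectified activation
  maps are weighted position-wise by their own rectified class gradients
  and summed over channels, upsampled bilinearly to the input grid with
  each map cell aligned to the centre of its receptive field (tracked
  through the conv/pool stack), and multiplied elementwise with the guided
  backpropagation map. Position-wise weighting is used instead of the
  classic spatially-pooled channel weights because these networks end in
  fully connected heads, not global average pooling; pooled weights lose
  spatial localisation there (they demonstrably fail to highlight the
  nucleus on this package's own classifiers).

Raw map values are what tests assert on; rescaling to [0, 1] happens only
in `normalize_for_display`.

## Evaluation

Confusion matrices count truth (rows) against prediction (columns);
accuracy is trace over total; precision and recall are one-vs-rest, with
zero-denominator cases reported as undefined (`None`), never as 0. Count
agreement uses Pearson's r with a Fisher-z 95% CI and two-sided p;
zero-variance vectors are flagged undefined.

## Problem sizes and known limitations

* Field-scale experiments run on reduced fields (128x160 to 224x288 px,
  8-40 nuclei) rather than full 4032x3072 stitches; full-size generation
  works but stride-1 scanning a full well is out of desk-scale CPU reach.
* The stage-2 count regressor is data-hungry: with the few dozen score
  maps a desk run can generate (plus count-preserving flip augmentation)
  it reaches ~10-15% mean absolute percentage error, versus ~1-2% for the
  object-level tally; hundreds of training maps would be needed to close
  the gap. The library supports it; the counting results quoted by the
  acceptance run use the object-level route.
* The necrotic class saturates the 16-bit range by design; pipelines
  sensitive to saturation should lower `peak_intensity`.
* The engine is single-threaded numpy; it is fast enough for every test
  and example here but is not a general-purpose training framework.
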