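# Methods

## Model

A section is a set of N spots, each pairing a P×P RGB patch Xᵢ (centered
on the spot's pixel coordinate; off-slide area padded constant white, the
color of H&E background) with a d-dimensional expression target yᵢ. The
predictor has three stages.

**Backbone F.** `tiny_cnn` is three 3×3 stride-2 convolution + ReLU
blocks (channel widths c, 2c, 4c with 4c = `embed_dim`, default 32)
followed by global average pooling. `residual_cnn` interleaves two
identity-skip residual blocks (two 3×3 convs each, relu(x + C₂(relu(C₁(x))))
with stride-2 stem/downsample convolutions — a desk-scale residual
network; it is the package's own compact design, sized so that training
on a few hundred spots takes seconds, not a pretrained classifier.
`backbone_kind="none"` is the backbone ablation: a frozen random linear
map of the 8×-average-pooled grayscale patch, so only the head trains.
Inputs are scaled to [−0.5, 0.5]; weights are He-initialized from the
training seed.

**Head G.** A two-layer fully connected refinement map,
embedding → `hidden_dim` (default 64) → d, ReLU between. G outputs gene
space directly, so the attention stage operates on expression-scale
vectors.

**Spot attention A.** With fx the N×d matrix of per-spot predictions and
Q = K = V = fx,

A(Q,K,V) = softmax(QKᵀ/√d)·V, d = number of columns of K (= genes).

The softmax is row-wise with per-row max subtraction (a pure overflow
guard; mathematically a no-op). The module has no learned parameters: no
Q/K/V projections, no heads, no positional encoding. Its effect is a
row-stochastic mixing, so each attended prediction is a convex combination
of the direct predictions, weighted toward spots with similar predicted
profiles. With one spot it is the identity; it is equivariant to spot
permutation.

**Loss.** L = L_mse + L_mse′, where L_mse is the mean squared error of the
direct predictions over all N·d entries and L_mse′ that of the attended
predictions. The two terms are summed with equal weight; the reported
total is exactly their sum. A sum-of-unsquared-L2-norms variant is
available (`loss_flavor="l2norm"`) for sensitivity checks. With the
attention branch disabled the attended term is zero and L reduces to
L_mse; no gradient flows through the attention path.

All gradients — including the attention backward pass, which carries
three terms (through V and through Q and K inside the scores) — are
hand-derived and verified against central finite differences in the test
suite.

## Preprocessing

Fixed order, applied to a train/test section pair jointly: (1) restrict
both sections to the (lexicographically sorted) intersection of their gene
universes; (2) drop spots with zero total count (logged; the scale factor
is undefined for them); (3) scale each spot to `target_sum` total counts
(default 1e4, the community convention for spot-level data) and log1p;
(4) rank genes per section by plain variance of the normalized values
(ties broken by gene ID), take each section's top `n_hvg`, and restrict
both sections to the union; (5) batch-correct. The built-in correction
(`center_scale`) removes each section's per-gene mean and divides by the
pooled per-gene standard deviation (zero-variance genes divided by 1);
`external_harmony` is a hook slot for a user-supplied callable — the
Harmony algorithm itself is deliberately not reimplemented here — and
`none` skips correction. Per-gene Pearson correlation is invariant to
per-gene affine maps, so the choice between `center_scale` and `none`
does not change the evaluation; it changes the optimization scale.

Patch size is defined in pixels (default 224, the conventional encoder
input; 64 in the desk-scale example) independent of the image's
micron-per-pixel scale.

## Training and inference

Adam (β 0.9/0.999), default learning rate 1e-4 and 50 epochs as library
defaults; the desk-scale example uses 1e-3 for 250 epochs, which is where
the dual objective reaches its plateau on 256-spot sections — the
attended branch converges noticeably more slowly than the direct one,
because useful mixing weights only emerge once the direct predictions
carry signal. Minibatches are spot subsets (default 128); during training
the attention mixes within the current minibatch
(`attention_scope="batch"`), or over the whole section with one
full-batch step per epoch (`"section"`). At inference the attention is
always applied once over all spots of the query section jointly — the
module is transductive: a section is predicted as a whole. Prediction and
attention at inference run in double precision so results are invariant
to spot order at 1e-12 resolution.

All randomness (initialization, shuffling) derives from the config seed;
runs are bitwise reproducible on CPU, and the pipeline's `report.json`
is byte-identical across reruns of the same config.

## Evaluation

Per-gene PCC across the held-out section's spots; R̄ averages the genes
with defined PCC (a gene with zero variance in either vector is excluded
and counted in `n_undefined`, not coerced to 0, which would bias the
mean). R̄₅₀ averages the top `k_prime` (default 50) genes ranked by mean
*predicted* expression, descending, ties lexicographic; ranking on
observed expression is available as a sensitivity flag. When the panel
has fewer than `k_prime` genes the rank cutoff clamps to the panel size.

## Synthetic benchmark

The generator emulates the structure the method needs, at desk scale:

- **Tissue.** Each section carries `n_latent` (4) latent factors on an
  `n_rows`×`n_cols` (16×16) grid, composed of a discrete and a smooth
  part: the grid is partitioned into `n_regions` (4) contiguous
  equal-count regions (quantile bins of a smoothed random field), each
  region with its own latent profile — the analogue of anatomical regions,
  whose presence is what makes averaging over highly correlated spots a
  sensible operation — plus a weaker smooth continuum
  (`continuum_strength` 0.5 vs `region_strength` 1.5; Gaussian-smoothed
  white noise with length scale `spatial_length_scale` = 3 spot units;
  an exact squared-exponential GP mode exists for small grids). Region
  profiles and gene loadings are shared between the two sections (shared
  biology); geometry and field draws are independent.
- **Expression.** Nonnegative loadings (each gene loading mainly on one
  factor), softplus link, per-spot composition scaled to `count_depth`
  (5000) expected counts, negative-binomial noise with dispersion 10
  (Poisson in the infinite-dispersion limit). Section 2 receives an
  additive per-gene batch shift on log-rates (`section_shift` 0.3).
- **Image.** White slide; each spot sits in an eosin-pink disc whose RGB
  levels encode three factors (sigmoid-squashed, swing 130 of 255) and
  which contains dark hematoxylin-like blobs whose count encodes the
  fourth. Latent-independent noise emulates staining variability:
  per-spot stain jitter (σ 56 per channel), blob-count jitter and
  per-pixel speckle, all scaled by `image_noise` (1.0). At
  `image_encoding_strength` 0 the discs carry jitter but no signal — the
  negative control.

What the generator does **not** emulate: staining artifacts, tissue
folds, fiducials, cell-scale morphology, platform-specific spot geometry,
or gene-gene regulatory structure beyond the shared factors. Passing
controls on this data show the pipeline learns image-encoded factors and
that the attention stage behaves as designed; they do not certify
real-tissue accuracy.

Benchmark conditions (the defaults above, with 64 px patches, 30-gene
HVG rank per section, 250 epochs, seeds 1–5) place held-out R̄ around
0.4–0.7 with spot-level prediction noise large enough that the attention
stage has something to average away; the no-image-signal control sits
within ±0.1 of zero. Under these conditions the full model matches or
beats the no-attention ablation on most seeds; the margin is small, as
expected for a denoising stage.

## Numerical choices and edge cases

- Softmax with per-row max subtraction; attention rejects non-finite
  inputs.
- Counts must be nonnegative integers at the type level; fractional or
  negative "counts" are construction errors.
- Empty gene set on write, zero-total spots on normalize, HVG request
  exceeding the gene count, shape-mismatched loss inputs, and
  out-of-slide spot centers are all hard errors naming the offender.
- Ties in HVG and HEG ranking break lexicographically by gene ID, making
  both selections deterministic under column permutation.
- Checkpoints store weights plus architecture, gene panel and a config
  fingerprint in one `.npz`; loading validates the format version.

## Known limitations

- Training a full-scale encoder (e.g. a 50-layer residual network at
  224 px on thousands of spots) is outside the intended envelope of the
  numpy engine; the package targets desk-scale experiments and method
  study. The architecture is the contribution under test, not the
  throughput.
- The attention stage helps when prediction errors are spot-local and
  the tissue has groups of truly similar spots; on near-noise-free inputs
  or cluster-free tissue it degrades gracefully toward a mild smoothing
  penalty.
- No stain normalization or augmentation; no HDF5 matrix reader; Harmony
  only as an external hook.
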