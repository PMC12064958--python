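# Methods

This note documents the models, parameters and design choices behind
octa3d: what the phantom emulates and deliberately does not, how the
label/synthesis/training pipeline is defined, the numerical conventions,
and the known limitations. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

A flow volume is a float array in `[0, 1]` with axes `(z, y, x)` =
(depth, slow scan, fast scan). A C-scan slice is `volume[z]`; a B-scan
is `volume[:, y, :]`; an en face image is a maximum intensity projection
(MIP) over a depth slab. `[0, 1]` is the canonical range everywhere; the
network module alone maps to/from the tanh range `[-1, 1]` at its
boundary (`x ↦ 2x − 1`), because the vascular metrics are
range-sensitive and a single canonical range prevents silent scale bugs.
On disk, volumes are multi-page TIFF or `.npy` (uint8/uint16 scaled by
1/255 or 1/65535, or raw float32); writing refuses out-of-range values
rather than clipping.

Rigid transforms are 3×3 homogeneous matrices in (row, col) convention
mapping reference coordinates to the moving frame; the phantom returns
the transforms it applied so registration can be tested against a known
truth.

## The phantom

The phantom generates the statistical structure the method assumes, not
OCT physics:

* **Vasculature** — `n_trees` (default 8) biased 3D random walks with
  Bernoulli bifurcation (`branch_prob` 0.04/step, up to 3 generations),
  dilated by spherical elements with per-branch radii drawn from
  `radius_range` (1–3 voxels). `lateral_bias` (0.85) suppresses the
  axial component of the walk, giving the predominantly in-plane vessels
  that motivate C-scan-plane processing. Tree *i* always consumes random
  substream *i*, so raising `n_trees` only adds vessels — the basis of
  the density-monotonicity property test.
* **Signal** — vessel voxels carry
  `vessel_intensity · exp(−attenuation_coeff · z)` (defaults 0.45 and
  0.015/voxel). The peak reflectivity is kept well below 1 so that
  multiplicative speckle rarely saturates the clipping range; saturated
  vessels would look artificially uniform and corrupt every contrast
  comparison.
* **Noise** — multiplicative unit-mean gamma speckle with shape
  `speckle_shape` (2.0 → variance 0.5) and additive gamma background
  with mean `background_level` (0.08), both clipped to `[0, 1]`. Both
  fields are drawn on a coarse grid and block-replicated over
  `speckle_grain` = (8, 2, 2) voxel cells. The lateral grain gives the
  granular texture of coherent imaging; the axial grain is set at the
  scale of a vessel caliber so a depth column crosses O(1) independent
  speckle grains. This matters: with voxel-independent noise, a maximum
  projection over a slab takes the max of many independent draws, which
  biases both the background pedestal and the vessel brightness upward
  — the averaged en face label would then be a *worse* estimate of the
  underlying reflectivity than the degraded input, contradicting the
  premise that averaged projections approximate truth. With grains of
  vessel-caliber extent, en face MIPs are approximately unbiased and the
  label-as-ground-truth construction is coherent.
* **Repeats** — each acquisition applies an independent in-plane rigid
  drift (uniform within `max_shift` = 4 px, `max_rotation` = 2°,
  identical for all depths, as whole-volume subject motion would be)
  followed by independent noise. The motion model is rigid only; the
  tissue-distortion component of real motion is out of scope, since
  rigid drift suffices to exercise registration.
* **Avascular slices** — pure background + grain, the C component of
  input synthesis.

Passing tests on this phantom show the pipeline's machinery is correct
under the stated statistical assumptions; they do not certify
performance on real OCTA, whose speckle statistics, decorrelation noise
and non-rigid motion the phantom does not model.

## Reference labels

Ten repeats are projected to en face images, registered to repeat 0 and
averaged. Registration detects SIFT keypoints on lightly
Gaussian-smoothed copies (σ = 1.5 px — granular noise otherwise swamps
the descriptors; the warp is applied to the originals), matches with a
0.75 ratio test plus cross-check, and fits a rigid transform by RANSAC
(minimal 2-point samples, 2 px residual threshold, deterministic seed).
If the strict ratio leaves too few matches or no consensus, one retry at
ratio 0.9 is attempted; the accepted model is then refined by a
least-squares fit over all loose-ratio matches consistent with it. An
image that still yields no model raises a registration error naming its
index — pure-noise inputs fail rather than silently passing through.

Warped images are resampled bilinearly; a pixel is valid only if its
source center lands inside the frame, and all images are cropped to the
largest axis-aligned rectangle valid in every repeat (maximal-rectangle
algorithm), so averaging never dilutes with padding. Averaging is the
plain pixel mean of the raw `[0, 1]` images; no per-repeat intensity
renormalization is applied before averaging, keeping the label on the
acquisition scale.

## Input synthesis and the training set

`S = norm(α·E + β·C)` with per-image min–max normalization; a constant
weighted sum maps to the zero image (all-black inputs are a sanctioned
training class, so the degenerate case is defined rather than an error).
Min–max makes the (α, β) trade-off scale-free — only the ratio matters —
which the suite checks as an invariance property. Defaults α = 0.25,
β = 0.75. Each vascular pair draws its noise image uniformly with
replacement from the avascular pool at dataset-build time (fixed per
pair); augmentation is redrawn each epoch. The full-scale recipe is 350
training pairs plus 20 noise-only and 20 black pairs with 50 held out;
desk-scale experiments keep the class structure at 50 + 5 + 5 with 10
held out.

Augmentation applies the same transform to input and label: a rotation
by a multiple of 90° (interpolation-free) and a crop-then-resize with
integer crop side drawn from `[0.75·n, n]` (the full-frame draw leaves
the pair bitwise unchanged). Non-square inputs are rejected.

## The network and training

Generator: `n_levels` stride-2 downsampling blocks
(conv 4×4/s2/p1 → norm → LeakyReLU 0.2) to a bottleneck, then mirrored
transposed-conv blocks (→ norm → ReLU) with channel-concatenation skip
connections and a final transposed conv + tanh. Channels double from
`base_channels` to a `max_channels` cap (64→512 at full scale, 8 levels
for 256×256 with a 1×1 bottleneck; 16→64 and 6 levels for the 64×64
desk scale). The entry block carries no norm (raw image statistics) and
neither does the bottleneck (1×1 maps have no spatial statistics).
Discriminator: entry conv + LeakyReLU, `n_blocks` conv blocks with norm
(5 at full scale reduce 256→1×1 through the final 4×4/s2/pad-0 conv +
sigmoid; 3 blocks at 64×64).

The discriminator is unconditional — it scores a lone image, never the
(input, output) pair — exactly as the loss definitions are written; a
`conditional` flag is reserved on the spec for the input-conditioned
variant, which is not implemented.

Normalization at batch size 1: what batch norm computes at batch 1 is
per-channel spatial standardization, so the layer normalizes each sample
by its own spatial statistics during training while maintaining
exponential running statistics (momentum 0.1) that are frozen for
inference — a trained generator is therefore deterministic at apply
time. Optimizer: Adam, lr 10⁻³, betas (0.5, 0.999) (the adversarial
convention; unstated elsewhere), ε = 10⁻⁸. λ = 10³ weights the L1
content loss against the adversarial term; every log is clamped at
10⁻⁷. Each sample triggers one discriminator step (real label, then the
detached generated image) and one generator step (λ·L1 gradient plus the
adversarial gradient backpropagated through the discriminator, whose own
gradients are discarded). Per-epoch sample order and augmentation seeds
derive from `(seed, epoch)`, so resuming from an epoch checkpoint
(weights + Adam moments in one `.npz`) reproduces the continuation
bit for bit. A non-finite loss aborts with the epoch/step.

Desk-scale training conditions used by the tests and acceptance script:
64×64 pairs, 50 vascular + 5 noise-only + 5 black, 30 epochs, batch 1,
lr 10⁻³, λ = 10³, generator 6 levels / base 16 / cap 64, discriminator
3 blocks — sized for single-CPU runs of a couple of minutes. The
engine computes in float32 for training and float64 in the
finite-difference gradient checks.

## Volumetric enhancement

The generator is applied to each C-scan slice independently with frozen
normalization statistics; slices are reflect-padded to the required
size multiple (reflect, not zero, so border vessels are not attenuated
at the pad seam) and cropped back exactly. Slice independence is tested
by permutation and zeroing oracles. Per-slice wall-clock timings can be
collected; no throughput claim is made.

## Metrics

"Global adaptive threshold" is implemented as Otsu's method (the cited
technique class fits the bimodal vessel/background histograms);
constant images raise a degenerate-input error. Skeletons come from
standard 2D morphological thinning; exact pixel counts on fixtures are
pinned from that implementation and marked algorithm-dependent. CNR uses
population (not sample) standard deviations, matching the brute-force
oracle convention. VC counts 8-connected components and reads "five
continuous pixels" as component size ≥ 5, not path length. For
`evaluate_image`, the binarized white region is the signal and its
complement the background.

Per-B-scan CNR binarizes each B-scan independently and takes a stated
avascular depth band as background, excluding (with a warning) band
pixels that land in the detected signal mask. One behavior deserves
emphasis: on a volume with *no* vessels, the adaptive threshold still
splits the noise at its upper tail, so the reported CNR reflects pure
selection bias (≈ 2 for the default noise model) rather than falling to
zero. No threshold-quality statistic we evaluated (e.g., Otsu's
effectiveness ratio) separates vessel-free from vessel-bearing frames on
this noise model, so no automatic vessel-free-frame guard is applied;
interpreting per-B-scan CNR requires knowing that frames genuinely
contain signal.

## Limitations

* The phantom's gamma/grain noise is a stand-in; the method's behavior
  on real OCTA speckle and decorrelation noise is untested here.
* Registration is rigid; elastic tissue distortion is out of scope.
* The full-scale recipe (256×256, 120 epochs, 400 acquisition sets) is
  defined in the configuration defaults but exercised only at desk
  scale; absolute metric values from the original clinical cohort are
  not reproducible without that data.
* The adversarial term at λ = 10³ is a small perturbation on the L1
  objective in the desk-scale runs; its qualitative effect on texture is
  not separately quantified.
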