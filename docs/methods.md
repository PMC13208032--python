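# Methods

`doseup` implements weakly aligned dose-up translation for low-dose
contrast-enhanced CT: given routinely acquired scan pairs whose anatomy
does not correspond voxel-for-voxel (respiration, posture, the interval
between acquisitions), it builds registration-based pseudo-references
(RPRs), trains a structure-preserving translation network against them,
and evaluates the result with reference-anchored, distributional and
region-level criteria. This note records the model, the committed
parameter values, the numerical choices, and what the synthetic study
conditions do and do not establish.

## Problem setting

Three acquisition domains are involved: a non-contrast scan (Pre, dose
fraction κ = 0), a low-dose contrast scan (Post40, κ ≈ 0.4) and a
full-dose scan (Post100, κ = 1). The task is to map a Post40 slice to its
full-dose appearance. Because repeat acquisitions are only weakly
aligned, voxel-wise supervision against the raw Post100 scan would
penalize anatomy for being in the wrong place; instead the Post100 scan
is deformably warped into the geometry of the fixed (Pre or Post40) scan
and the warped image — the RPR — serves as the supervisory anchor. An RPR
is an anchor, not ground truth: it inherits residual registration error,
so evaluation combines reference-anchored fidelity with distributional
and region-level criteria rather than trusting pixel fidelity alone.

## Preprocessing

Volumes are read from NIfTI-1 or DICOM series into Hounsfield units
(DICOM rescale slope/intercept applied; mixed-orientation series are
rejected). The chain is: soft-tissue window (center 40 HU, width 400 HU)
clipped and mapped affinely to [0, 1]; linear resampling to
0.5 × 0.5 × 2.0 mm; per-slice center crop / zero-pad to a 512 × 512
canvas; bilinear resize to the training size (default 256 × 256;
corner-aligned sampling so constants are preserved exactly). Crop/pad is
geometrically centered with odd remainders going bottom/right.

Slices of two acquisitions are paired by absolute physical z-coordinate:
each fixed slice takes its nearest moving slice, ties resolving to the
lower z; a fixed slice participates only if its nearest moving slice is
within half the moving slice spacing (the moving z-range extended by
dz/2 at both ends) — surplus cranial/caudal slices drop out. Pairing is
fixed-driven: a moving slice may serve several fixed slices.

Evaluation images are quantized to 8 bits with round-half-away-from-zero
(`round(255·v)`), the convention all metrics consume; feeding unit-domain
floats into a metric raises a `TypeError` rather than silently changing
the result.

## Hybrid registration (RPR construction)

**Stage 1 — global alignment.** A 3-level multi-resolution pyramid
(shrink factors 4/2/1) with the committed per-level iteration schedule
(100, 70, 20). The backend is pluggable; the built-in default is
symmetric-forces diffeomorphic demons (SimpleITK) with histogram matching
of the moving image to the fixed image beforehand, which absorbs the
global cross-dose intensity shift that pure intensity forces cannot
handle. Demons smoothing defaults: displacement-field σ 3.5 px,
update-field σ 2.5 px — chosen so the recovered field matches the
smoothness scale of respiratory/postural deformation rather than chasing
noise. A Mattes-mutual-information B-spline free-form-deformation backend
(`backend="ffd_mi"`) is available for strongly multi-modal pairs (its
optimizer budget is the sum of the schedule, since the underlying
optimizer does not expose per-level iteration counts), and
`register_backend()` accepts an external adapter (e.g. an SyN
implementation) when one is installed.

**Stage 2 — feature-level refinement.** Contrast-robust patch descriptors
are matched by a two-phase instance optimization in the spirit of
discrete-initialized Adam refinement:

1. *Discrete phase*: descriptor correlation is evaluated over integer
   control-node offsets in a ±3-node window around the initialization;
   the arg-max field is Gaussian-smoothed (σ 1 node) — a smoothing-based
   convex relaxation of the discrete solution.
2. *Continuous phase*: Adam (1000 iterations, learning rate 3.0 px,
   cosine-annealed to zero so the iterate actually settles instead of
   orbiting the minimum) refines the control-point field, minimizing
   feature dissimilarity plus a diffusion regularizer with weight 2.0.
   The regularizer acts twice, deliberately: as an explicit
   neighbor-tether gradient (without it, Adam's scale-free steps turn
   gradient noise into a spatial random walk) and by operator splitting —
   after each step the control field is Gaussian-smoothed with
   σ² = smooth_weight / 2 node units, the convolution form of an implicit
   diffusion step. In the infinite-weight limit the field becomes exactly
   spatially constant; at weight 0 nodes are independent.

Two safeguards matter in practice. Descriptors from structureless image
regions carry no matching information, so each node gets a saliency
weight from local gradient energy (soft threshold at the image's mean
node energy); low-confidence nodes keep their initialization. And because
descriptors are band-limited at the node stride, sub-pixel residuals
produce no reliable matching signal — a *verification gate* therefore
keeps a node's refined displacement only when it bought a clear
descriptor-matching gain (default 0.05 cosine-cost units) over the
initialization, snapping back otherwise. On pairs the global stage has
already aligned to sub-pixel accuracy the refinement then returns its
initialization exactly, and it engages only on genuine multi-pixel
residuals. Without the gate the refinement *degrades* well-aligned pairs,
which is the failure mode the hybrid-no-worse acceptance property guards
against.

The built-in extractor is a hand-crafted multi-scale gradient-orientation
histogram descriptor (HOG/dense-SIFT family): per node, magnitude-weighted
orientation histograms over the 2 × 2 half-patch cells of a 14-px window
plus a 2× larger pooled neighborhood, Hellinger-mapped and L2-normalized —
so a global intensity rescaling cancels exactly, giving the
contrast-robustness the cross-dose setting needs. Descriptors live on a
node grid with configurable stride: stride = patch (14) tiles the image
(a 256-px side pads to 266 and yields 19 nodes); the refinement default is
stride = 7 (half-patch overlap) so the control grid can resolve
displacements below a patch. A pretrained vision-transformer patch
embedder (patch 14, dimension 1024) plugs into the same interface where
its weights are available; the optimization code is identical either way.

**Composition.** With the pull-back convention `warped(x) = moving(x +
u(x))`, the composite is `u(x) = g(x + r(x)) + r(x)` (refinement `r` maps
the fixed grid into the globally aligned frame, the global field `g`
carries it on into the moving frame), and the RPR is the moving image
resampled **once** through the composite field. Alignment QC reports NCC
(Pearson), single-scale SSIM (Gaussian window σ 1.5, K1 0.01, K2 0.03)
and mean forward-difference gradient error per slice, plus a Jacobian
fold fraction for the field.

## Translation network and objective

The generator is the ResNet-style encoder/bottleneck/decoder of the
contrastive-translation family: 7 × 7 stem, two stride-2 downsampling
convolutions, 9 residual blocks at full scale, nearest-neighbor-upsample +
convolution decoder, instance normalization, reflect padding, tanh output;
1-channel unit-domain slices are mapped to [-1, 1] internally. The
discriminator is the standard 70 × 70-receptive-field PatchGAN (4 × 4
kernels, strides 2,2,2,1,1 — receptive field 4 → 10 → 22 → 46 → 70). The
contrastive feature net projects sampled patch vectors from nine tap
layers (the input plus eight encoder-side activations) through per-layer
2-layer MLPs with 256 channels, L2-normalized.

The generator objective is

    L = 1.0·L_adv + 0.1·L_SRC + 0.2·L_HDCE + 15.0·L_pyr + 2.0·L_edge

with every term a mean, so the weights are scale-free:

* **L_adv** — least-squares GAN loss (the family's convention; the form
  is switchable). The RPR plays the "real" sample for the discriminator.
* **L_pyr** — pyramid L1 over 4 dyadic scales with uniform per-scale
  weights; each level 2× average-pools the *generated output* and the RPR
  (one generator forward per step, rather than running the generator on
  downsampled inputs — the cheaper of the two readings of a multi-scale
  constraint, and the one a single forward pass admits).
* **L_edge** — mean absolute disagreement of forward-difference gradients
  (both axes, replicate boundary: the trailing difference is zero) plus
  4-neighbor Laplacians (edge-replicated padding). Both operators
  annihilate constants, so a global intensity offset costs nothing.
* **L_HDCE** — hard-negative decoupled patch contrastive loss: 512 patch
  locations per step, shared between the input's encoder features and the
  re-encoded output's, projected and normalized. Per query, an
  InfoNCE-style loss whose denominator excludes the positive (decoupled)
  and re-weights negatives by `exp(β·sim)` normalized to unit mean
  (β = 1.0, temperature 0.07). In the infinite-temperature limit the loss
  tends to `log(K−1)` for K sampled patches.
* **L_SRC** — semantic-relation consistency: Jensen-Shannon divergence
  between the row-softmaxed (temperature 0.07) patch-patch similarity
  matrices of input and output features; zero iff the relation structures
  agree. The exact HDCE/SRC formulations are fixed here by choice — the
  upstream literature names the components without pinning every
  constant; all constants live in `TrainConfig`.

Training alternates discriminator and generator+feature-net Adam steps
(β₁ 0.5, β₂ 0.999, constant lr 2 × 10⁻⁴, batch 16, 40 epochs at full
scale). Divergence (a non-finite loss) aborts with the last good
checkpoint restored. Knowledge transfer is two-phase: Phase 1 learns
Pre → Post100 on the abundant cohort; Phase 2 fine-tunes Post40 → Post100
from the Phase-1 checkpoint (`init_from` clones the checkpoint rather
than mutating it). Batch order, patch sampling and initialization derive
from the config seed, so a run is reproducible bit-for-bit.

The networks run on an in-repo reverse-mode autograd over numpy
(`doseup.nn`): broadcast arithmetic, matmul, im2col/BLAS 2-D convolution
with a transposed-convolution backward, pooling, padding (zero, reflect,
edge), patch gathering and the usual nonlinearities, each op's
vector-Jacobian product verified against finite differences in the test
suite. Everything is float32 CPU code.

## Evaluation suite

All metrics consume 8-bit images. PSNR/MSE use I_max = 255, with an
infinite-PSNR sentinel at MSE = 0 (flagged, excluded from means).
MS-SSIM uses 5 dyadic scales with the conventional weights (0.0448,
0.2856, 0.3001, 0.2363, 0.1333), Gaussian window σ 1.5, negative
contrast-structure terms clamped at zero; images too small for 5 scales
are scored with fewer scales under a warning, never silently. FID fits
Gaussians to pluggable embeddings (production: an Inception-style
embedder; hermetic default: a seeded random projection) and takes the
Fréchet distance with the matrix square root by symmetric
eigendecomposition, negative eigenvalues clamped. The LPIPS-style
perceptual distance channel-normalizes per-layer features of a pluggable
convolutional backbone (hermetic default: a fixed seeded conv stack),
averages spatially and sums over layers. Grayscale inputs are replicated
to exactly three identical channels at the embedder/backbone boundary.

CNR follows the input-anchored protocol: `|μ_sig − μ_ref| / σ_ref` with
the signal mean from the evaluated image but the reference-tissue mean
and standard deviation (epaxial muscle) always measured on the *input*
image — a model cannot inflate CNR by suppressing reference variance.
σ_ref = 0 yields a flagged missing value, never infinity. A region's
polygons are pooled within a slice before statistics.

ROI polygons use the LabelMe JSON dialect ((x, y) pixel vertices; labels
mapped onto the region vocabulary — aorta, caudal vena cava, hepatic and
portal veins, spleen, liver, kidney cortex, epaxial muscle — with
unknown labels preserved and flagged, sub-3-vertex shapes skipped).
Rasterization is center-of-pixel and boundary-inclusive, with multiple
polygons combined under the even-odd rule: disjoint ROIs union; a
polygon nested inside another (a traced hole, e.g. a vessel running
through an organ) is carved out. A square polygon whose corners sit on
pixel centers contains exactly the spanned pixels.

Distribution similarity between ROI intensity samples: KL divergence over
64-bin histograms on [0, 255] with 1e-10 additive smoothing, direction
P = generated, Q = RPR (bin count, smoothing and direction are fixed here
by choice); Wasserstein-1 via the empirical quantile integral of the raw
samples. Vessel profile consistency: Pearson correlation of intensity
profiles along the line through the region centroid in the direction of
the minor principal axis of the rasterized region, extended to 1.5× the
region's extent, sampled at pixel spacing with bilinear interpolation
(the profile protocol is likewise a committed choice; alternatives plug
in). Aggregation reports mean (sd) per metric and Welch's
unequal-variance t-test with Welch–Satterthwaite degrees of freedom,
two-sided, α = 0.05.

## Synthetic phantom (study conditions)

Real three-dose veterinary abdominal data are private, so the test bed is
a 2.5-D phantom: ellipse primitives on a body ellipse — large
moderate-enhancement parenchymal blobs (liver, spleen, kidney cortex),
small high-enhancement vascular disks (aorta, caudal vena cava, hepatic
and portal veins), and a non-enhancing paraspinal muscle pair as the CNR
reference. Per region, mean attenuation follows
`HU = baseline + κ·enhancement` with fixed shipped tables (muscle
baseline 55 HU, enhancement 0; aorta enhancement 300 HU at κ = 1; vessels
largest, parenchyma moderate, background none). Defaults: 256-px grid,
1 × 1 × 2 mm spacing, additive Gaussian noise σ 8 HU, a smooth frozen
parenchymal texture (σ 6 HU, 8-px scale, identical across doses, absent
from vessels so the dose law holds exactly there), seeded per-subject
dose jitter ±0.1 reproducing the uneven-enhancement regime of real
low-dose scans, geometry drifting slowly along z. Misalignment is a
per-slice smooth random displacement field (Gaussian scale 20 mm, maximum
magnitude 4 mm — surrogates: the source data specify only the acquisition
interval, not a deformation magnitude), applied with the pull-back
convention and returned so recovery is measurable; amplitudes that fold
the grid are rejected. Landmarks are seeded points in the eroded body
interior; their warped positions come from fixed-point inversion of the
pull-back field.

What the phantom does not emulate: projection-domain physics, iodine
pharmacokinetics, 3-D deformation coupling across slices, anatomical
realism, scanner/kernel variation. Passing tests therefore establish that
the pipeline's machinery behaves as specified under controlled weak
alignment and a linear dose response — not that clinical image quality
gains transfer to real animals.

## Study scales and committed conditions

The acceptance studies run at sizes a single CPU handles in minutes, as
the package's own smoke-scale protocol: registration recovery on 20
seeded 128-px pairs with the default 4-mm/20-mm misalignment; training
studies at 64-px slices with a narrow network (10 generator/discriminator
base channels, 3 residual blocks, batch 4, 64 contrastive patches,
200-iteration runs; knowledge-transfer comparisons at an equal 70-
iteration Phase-2 budget after a 150-iteration Phase-1 pretrain). The
full-scale defaults (256 px, width 64, 9 blocks, batch 16, 512 patches,
40 epochs) remain the committed configuration for real runs.

## Known limitations

* Stage-2 refinement is conservative by design: on pairs the global stage
  aligns to sub-pixel accuracy the gate returns the initialization, so
  hybrid ≈ global there; its gains appear on multi-pixel residuals.
* The built-in descriptor is weaker than a pretrained ViT embedder;
  descriptor-starved (structureless) regions rely on the diffusion prior.
* The MI-FFD backend shares one optimizer budget across pyramid levels.
* 2-D slice-wise processing throughout; no volumetric consistency.
* The least-squares adversarial form, HDCE/SRC constants, KLD binning and
  the profile-line protocol are committed interpretations where upstream
  conventions are named but not fully specified; each is configurable.
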