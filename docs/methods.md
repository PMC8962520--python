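# Methods

## The phantom: what it emulates and what it does not

The generator emulates the statistical situation multi-frame OCT
enhancement relies on: a fixed underlying scene imaged repeatedly with
independent noise and small rigid inter-frame motion.

**Scene.** A 128×256-px B-scan (configurable, minimum 64×64) of ten tissue
classes stacked top-to-bottom: background, IPL, INL, OPL, ONL, ELM, IS-OS,
Inner-RPE, Outer-RPE, choroid, background. Layer boundaries share a shallow
parabolic foveal dip (default 6% of image height) plus a small low-order
per-boundary wobble, so they are smooth curves and thicknesses stay near
their defaults. Per-class mean reflectivities (background 0.05, IPL 0.55,
INL 0.25, OPL 0.55, ONL 0.18, ELM 0.60, IS-OS 0.70, Inner-RPE 0.30,
Outer-RPE 0.75, choroid 0.45) are chosen so each of the six CNR layer pairs
is well separated and positive on the clean image. Vertical vessel shadows
(six Gaussian attenuation bands, width 2–4 px, depth 25–50%, cast downward
from the inner retina) give the scene horizontal structure, as real macular
B-scans have; without any horizontal feature, sub-pixel horizontal
registration would be ill-posed on a pure layer-stripe image. A final
Gaussian blur (σ = 1 px) band-limits the interfaces. Optional lesions
(hypo-reflective fluid ellipses, hyper-reflective foci) perturb
reflectivity inside the tissue band only.

**Acquisition.** Frame i is the clean scene warped by a rigid motion drawn
uniformly within the given bounds (the reference frame keeps the identity;
the identity warp is short-circuited so zero-motion acquisition is
bit-exact), multiplied by i.i.d. unit-mean Gamma speckle, plus additive
Gaussian sensor noise, clipped to [0, 1]. With a configurable probability a
non-reference frame is replaced by a decorrelated pure-noise frame,
emulating fixation loss. True motions and loss indices are recorded.

**Noise defaults.** Speckle concentration (Gamma shape) 12 — relative
standard deviation ≈ 29%, strong fully-developed-speckle territory — and
sensor σ = 0.02. These were fixed by a coherence argument: under them,
ordinary repeated frames correlate ≈ 0.78 with the reference, so the
clinical 70%-correlation exclusion rule behaves as described in practice
(normal frames retained, decorrelated frames at ≈ 0.01 cleanly rejected).
A harsher speckle setting would put normal frames *on* the exclusion
threshold, which contradicts the protocol being emulated. The Gamma model
itself is a standard coherent-imaging approximation; no attempt is made to
calibrate it to any particular device, and the motion model is rigid-only
by construction.

**What passing tests do not show.** The phantom has no axial point-spread
function, no depth-dependent signal roll-off, no non-rigid deformation, no
vendor-specific post-processing, and its lesion repertoire is minimal.
Results on it demonstrate the correctness and relative ordering of the
methods under the stated noise model, not clinical-grade performance.

## Registration, exclusion, averaging

**Reference selection.** The frame maximising mean(tissue)/std(background),
with the tissue/background split by Otsu thresholding; an all-constant
frame has zero background spread and is treated as infinite SNR; ties break
to the lowest index.

**Rigid registration.** The transform (dx, dy, θ about the image centre)
maximising the similarity of the warped moving frame to the reference.
The objective is Studholme's normalised mutual information
(H(X)+H(Y))/H(X,Y) on a 32-bin joint histogram over [0, 1]: raw MI
evaluated on overlap regions grows spuriously as the overlap shrinks,
biasing translation search toward large shifts, while the normalised form
is stable. Both images are pre-smoothed (Gaussian σ = 1.5 px) to damp
speckle-induced local optima. Search: an exhaustive integer translation
grid at half resolution, repeated for a 5-point fan of candidate rotations
(a translation-only scan is blind to the vertical edge displacement that a
few degrees of tilt causes), then Nelder-Mead refinement of (dx, dy, θ) at
full resolution (xatol 0.02, soft penalty outside ±max_shift+2 px /
±max_rotation). Raw MI of the aligned pair is also computed and reported
per frame. Constant images make the histogram degenerate and raise an
error naming the input. Under default noise this recovers random
perturbations up to 10 px / 3° to within 0.5 px and 0.25° in ≥ 95% of
trials.

**Fixation exclusion.** A frame is excluded when the peak of its
normalised cross-correlation against the reference (both standardised to
zero mean and unit variance, peak searched within ±5 px) falls below 70% of
the reference's zero-lag autocorrelation, which is exactly 1 after
standardisation — i.e. NCC < 0.70. This zero-lag reading is the only
scale-free interpretation of the rule; the reference is never excluded.

**Averaging.** Pixel-wise arithmetic mean of the selected aligned frames,
in acquisition order after exclusion (how the k-subset is chosen is
otherwise unspecified; first-k is the deterministic choice). Warping is
bilinear with constant background fill, matching the phantom, to avoid
edge artefacts that would confound CNR.

## The enhancement network

One model per frame count k (k ∈ [1, 20] as an input-channel count); a
single variable-k model would complicate the first convolution for no
benefit at this scale.

Architecture (base channels c = 8 by default): a 3×3 stem (k→c); two
contracting blocks (stride-2 convolutions, c→2c→4c, each followed by a 3×3
convolution); a high-resolution representation stage holding two parallel
branches (1/4 and 1/8 resolution, 4c channels each) with two rounds of
cross-resolution fusion (per-branch convolution, then down-/up-projections
added crosswise); two expanding blocks with skip concatenations from the
encoder (nearest-neighbour ×2 upsampling + 3×3 convolution); a side path
concatenating the decoder features of both resolutions at full resolution
before a 1×1 projection; a 3×3 head with sigmoid. All activations are
LeakyReLU(0.1); weights are Xavier-uniform from the model seed. The output
is the residual blend `w · mean(inputs) + (1−w) · decoded` with
w = sigmoid(ρ) a learnable scalar initialised at 0.5 (a fixed-w mode exists
for testing; w = 1 bypasses the network exactly). Inputs whose sides are
not multiples of 8 are reflect-padded and cropped back.

The engine underneath is a small reverse-mode autodiff over float32 numpy
arrays (im2col convolutions, nearest upsampling, concatenation, separable
Gaussian filtering); its gradients are verified against finite differences
in the test suite.

**Loss.** `w_ce · BCE + w_ssim · (1 − SSIM)`, default weights (1, 1).
"Cross-entropy" on continuous [0, 1] intensities is read as pixel-wise
binary cross-entropy — the standard reading for image-to-image regression
with a CE loss; no mixing weight being specified anywhere, equal weights
are used. The SSIM inside the training objective is built from autodiff
primitives (11×11 Gaussian windows, σ = 1.5, c1 = 0.01², c2 = 0.03², valid
region), and matches the assessment SSIM to ~1e-8; the public
`combined_loss` computes its SSIM term with the assessment function itself
so the decomposition identities ((1,0) → BCE exactly, (0,1) → 1 − SSIM
exactly) hold to machine precision.

**Training.** Adam at 0.001; offline augmentation draws random
k-subsets of each stack's surviving frames; the monitored quantity is the
epoch-mean training loss (training rather than validation loss — the decay
rule's target is unspecified, and at this scale a held-out split would be
noisier than the signal). The baseline for the plateau rule is the loss of
the untrained model, so "no decrease within 10 epochs" counts from epoch 1;
after a decay (×0.9) the patience counter resets. An epoch counts as an
improvement only if it beats the best loss by 1e-6 — below that, float32
accumulation jitter across reshuffled batches is indistinguishable from no
change. Training is bit-deterministic given the config seeds. Channel
order sensitivity: the first convolution is not symmetric in its input
channels, so the output is only guaranteed order-invariant when the frames
are identical; with distinct frames, different orderings give (slightly)
different outputs, which is why frames are always fed in acquisition
order.

**Targets.** On phantoms the training target is the true clean scene. A
clinical study has no clean image and must use a 50-frame average as its
gold standard; a config switch (`gold_standard="avg-all"`) mimics that
setting by targeting the mean of all surviving frames instead.

## Assessment protocol

SSIM: scikit-image's `structural_similarity` with the canonical
parameters (11-px Gaussian window, σ = 1.5, c1 = 0.01², c2 = 0.03²,
data range 1). PSNR: 10·log₁₀(1/MSE) on data range 1, +∞ sentinel at zero
MSE. CNR: (h−l)/√(δ_h²+δ_l²) over pixels pooled from 50 pairs of 4×4-px
ROIs per layer pair; `auto_rois` places the windows on the ground-truth
label map at approximately equal horizontal intervals, each window fully
inside its layer, with the row drawn uniformly among feasible rows — an
automated, observer-free stand-in for manual marking, possible only
because the phantom's labels are exact. CNR is invariant under positive
affine intensity maps applied to the whole image, so it is comparable
across enhancement methods with different output scalings.

Weighted Cohen's kappa (via scikit-learn, with the full integer score
range passed as labels so ordinal distances are measured correctly even
when intermediate categories are unused): quadratic weights by default,
linear selectable; panels of more than two raters are summarised by the
mean of all pairwise kappas, with both weightings reported. Degenerate
inputs (all scores in one category for both raters) make the
chance-expected disagreement zero and raise an error rather than return a
conventional value.

## Experiment scales

The standard study conditions used by the tests and the acceptance script:
128×256 phantoms; 100 training stacks / 20 held-out test stacks for the
k = 5 network comparison (12 training epochs, batch 4, one augmentation
draw per stack — the loss curve is already far past its fast-descent phase
there); 50 trials for registration recovery; 20 replicates for the
averaging oracle and the exclusion check. Motion is disabled in the
training and sweep stacks (the aligned-acquisition setting registration
would otherwise produce) so the averaging-vs-network comparison isolates
denoising from registration error; the registration properties are
exercised separately with real motion. These sizes are the package's
defaults and are all configurable upward.

## Known limitations

- The phantom omits axial PSF, depth roll-off, shadow-casting pathology
  and non-rigid motion; absolute metric values here do not transfer to any
  clinical device.
- The registration search assumes the true motion lies within the
  configured bounds (±12 px, ±4° by default); larger motions are clamped
  by the soft penalty.
- One trained model serves exactly one frame count k.
- The numpy training engine is CPU-bound and intended for desk-scale
  geometries; it is not a route to training on full-resolution clinical
  scans.
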