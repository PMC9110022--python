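# Methods

## Problem setting

Hyperspectral microscopy of stained histology slides trades spatial
resolution for spectral resolution: a transmittance cube acquired at
87 bands (470–720 nm) is noisier and blurrier than the color image a
whole-slide scanner produces of the same tissue, and snapshot or
low-magnification hyperspectral acquisitions are coarser still.
`hsfuse` implements an unsupervised fusion approach: a network takes a
low-resolution hyperspectral patch (LR-HSI) and a co-registered
high-resolution RGB patch (HR-RGB) and synthesizes a high-resolution
hyperspectral patch, supervised only by the two inputs themselves —
no high-resolution hyperspectral ground truth is ever used.

## Pipeline

**Calibration.** Raw intensities are converted to transmittance with
white-reference and dark-current frames,
`T(λ) = (I_raw − I_dark) / (I_white − I_dark)` per pixel and band.
Pixels where the denominator falls below `eps = 1e-6` are masked to 0
and counted; output is clamped to [0, 1.2], preserving slight
super-unity noise while bounding the domain. The clamp ceiling and
`eps` are configurable; the library does not decide whether clamping
is applied again after reconstruction beyond the same ceiling.

**Registration.** The RGB image is registered onto the cube's
panchromatic (band-average) image by ORB keypoints, Hamming-distance
descriptor matching with a 0.75 ratio test and cross-check, and a
RANSAC affine fit (3-px reprojection threshold, up to 5000 keypoints).
Fewer than 3 robust inliers raises an error rather than silently
returning the identity. Warping uses bilinear resampling.

**Patching.** Aligned images are cropped by a sliding window (default
200 px window, 100 px step — a 2000×2000 frame yields 361 windows).
A patch is kept when at least half its pixels are tissue; a tissue
pixel is one whose panchromatic transmittance (or RGB luminance) falls
below τ = 0.9, since blank slide transmits near 1. The boundary case
(exactly 50%) is kept. LR-HSI patches are produced by exact S×S
block averaging ("box" kernel); non-divisible sizes are an error
unless cropping is explicitly requested.

## The fusion network

The HR-RGB channels are duplicated into a B-band stack — 35/35/17
copies of R/G/B at B = 87 — in wavelength-ascending contiguous blocks
(blue first; the camera grid starts at 470 nm, so the blue channel
carries the least in-range information and receives the fewest
copies). The LR-HSI is upsampled by a transposed convolution with
kernel (S+1)×(S+1) and stride S, concatenated with the stack along
the band axis, and passed through an encoder–decoder: six encoder
convolutions (3×3, widths 196, 256, 384/stride-2, 512, 640/stride-2,
768), two transposed-convolution upsampling stages with skip
concatenations from the matching encoder depths, decoder widths 640,
512, 256, 194, 160, 128, 96, and a linear 1×1 convolution back to B
bands. The 196-wide encoder layer and 194-wide decoder layer are
distinct layers with deliberately similar widths. ReLU follows every
convolution except the final 1×1; there are no normalization layers.
An S×S average-pool head (identical, by construction and by test, to
the box downsampling operator) re-degrades the output to LR.

Training minimizes `0.5·L_spatial + 0.5·L_spectral`, where
`L_spatial` is the MSE between the band-mean (panchromatic) images of
the stacked RGB input and the generated cube, and `L_spectral` is the
voxel MSE between the generated and input LR cubes. The optimizer is
Adam at 1e-4 with batch size 2; early stopping watches the validation
total loss with patience 2 (configurable) up to 13 epochs by default.
A width multiplier κ scales every internal channel count as
`ceil(κ·width)` so the same architecture runs at desk scale; κ = 1
reproduces the production table exactly. Weights are Glorot-uniform
initialized and fully seeded; two runs with the same seed, data and
configuration produce identical loss histories.

All tensor operations run on a compact reverse-mode autodiff engine
(`hsfuse.nn`) written on numpy: im2col convolutions and transposed
convolutions with Keras-style padding, pooling, dense layers, dropout,
and Adam/Adadelta. Every layer's analytic gradient is tested against
central finite differences.

## Quality metrics

PSNR and MAE are computed per band and averaged across bands (peak
value defaults to 1.0 for transmittance data; bands with zero MSE are
reported as +inf and excluded from the PSNR mean with a warning). MAE
is also reportable ×100 as percent. The spectral angle mapper (SAM)
is reported per-pixel-averaged by default — the community convention —
with the pooled single-angle form (square roots restored in the
denominator) available explicitly. SSIM here is the global
single-statistic form over whole-image means, variances and
covariance with c1 = (0.01·L)², c2 = (0.03·L)²; it is *not* the
sliding-window SSIM and the two disagree on non-stationary images.
Classification metrics are accuracy/sensitivity/specificity from
confusion counts (NaN sentinels on empty denominators) and a
rank-based (Mann–Whitney) ROC AUC with average ranks for ties.

## The patch classifier

The tumor/normal patch classifier follows the Inception-v4 layout
adapted to square patches: a three-convolution stride-2 stem
(87→90→94→96 channels at full width), 4 Inception-A blocks, a
Reduction-A, 7 Inception-B blocks, a Reduction-B, 3 Inception-C
blocks, global average pooling, and a 2-neuron sigmoid head trained
with per-neuron binary cross-entropy on one-hot targets (argmax for
class calls, the tumor neuron for ROC curves). Every convolution is
he_normal-initialized and followed by ReLU and 20% dropout. Training
uses Adadelta (lr 1.0, rho 0.95) at batch size 16 for 10 epochs by
default, with a hard guard that raises if any patient identifier
appears in more than one split.

Two square-kernel simplifications of the original Inception design:
the factorized 1×7/7×1 and 1×3/3×1 convolution pairs are folded into
single 3×3 convolutions of the same output widths, and the reduction
stages use valid-padding stride-2 kernels of 5 (Reduction-A) and 3
(Reduction-B) — the unique sizes that reproduce the production
25→11→5 spatial trace — capped at the feature size for small inputs.

Whole-slide probability maps average the per-patch tumor
probabilities over every pixel each patch covers (up to 4× coverage
at the default grid); uncovered pixels are NaN with coverage 0.

## Synthetic phantoms

Phantoms emulate one patch observed by both instruments. Absorption
is Beer–Lambert, `T = exp(−Σ_k c_k·ε_k(λ))`, with two Gaussian
absorptivity curves standing in for hematoxylin (600 nm center, 70 nm
width, amplitude 1.2; dominant in nuclei) and eosin (525/45/0.8;
cytoplasm). Nuclei are random ellipses (semi-axes 2–5 px) at density
0.01 px⁻²; cytoplasm concentration is a smoothed Gaussian field
(σ = 6 px) around 0.5; 15% of the patch is blank slide (all
concentrations zero, transmittance exactly 1). The degraded cube is
the clean cube blurred (Gaussian, σ = 1.5 px) plus per-band Gaussian
noise (sd 0.01 mid-band, ×4 at the first and last bands, emulating
sensitivity falloff at the spectral extremes); LR-HSI is the box
downsampling of the degraded cube by default. The RGB image is
rendered from the *clean* cube through Gaussian camera response
curves (610/540/480 nm, sd 30 nm, renormalized) — reproducing the key
asymmetry that the color image carries high-frequency detail the
hyperspectral cube lacks. Label-1 samples scale all stain
concentrations by (1 + δ), δ = 0.3 by default; δ = 0 makes labels
uninformative by construction. Everything is bit-deterministic given
the seed; dataset splits draw disjoint child seeds.

These phantoms are idealizations: Gaussian absorptivities instead of
measured stain spectra, no scattering, autofluorescence, chromatic
focus shifts, or spatially correlated noise, and far less anatomical
diversity than real slides. Passing desk-scale tests therefore
demonstrates mechanical and numerical correctness of the pipeline and
the qualitative fusion behavior, not clinical-grade reconstruction
quality.

## Desk-scale experiment sizes and findings

The scaled-down fusion experiment trains the 4× network at κ = 0.05
on 64 phantom pairs (32-px patches, 8 bands) with 16 validation and
16 held-out pairs — about 17k parameters and 32 optimizer steps per
epoch. The acceptance script trains to the validation-loss plateau
(up to 300 epochs, patience 10), mirroring the production stopping
rule ("stop when validation loss stops decreasing") at a comparable
step count; training reaches the analytic loss floor of the
objective. The classifier sanity experiment uses 480 strongly
separable phantoms (δ = 2) at 64 px and κ = 0.1 so that the five
prescribed epochs contain enough batch-16 Adadelta steps (~150) for
the optimizer to escape its initial collapse phase; 64-px patches
keep Inception-A feature maps at 8×8, avoiding the padding-dominated
regime that extinguishes inter-sample signal at smaller toy sizes.

A structural property of the unsupervised objective worth knowing
before interpreting spectral-fidelity numbers at desk scale: the
spatial loss constrains each pixel's band-*mean* and the spectral
loss each S×S block's per-band *mean*, so the within-block, per-band
structure of the output is not determined by the loss at all — it is
chosen by the network's inductive bias. With the production-scale
data volume and step counts this bias evidently favors
interpolation-faithful spectra; in the small regime the converged
model can match the loss floor while distributing panchromatic detail
incoherently across bands, which inflates the spectral angle against
ground truth and varies substantially with the weight-initialization
seed. The tests and the acceptance script report these angles exactly
as computed.

## Known limitations

- The autodiff engine is CPU/float32 and sized for desk-scale runs;
  κ = 1 forward passes at 200 px are possible but slow, and training
  at full width is out of reach by design.
- The ENVI dialect covers plain BSQ/BIL/BIP with standard headers,
  not vendor extensions.
- The global SSIM form saturates near 1 for images with matched
  global statistics regardless of local structure; use it only as the
  panchromatic-similarity statistic it is defined to be.
- Probability-map stitching averages overlapping patch probabilities
  uniformly; no distance weighting.
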