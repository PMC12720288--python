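# Methods

`cminr` estimates a volumetric MR image from a fully-sampled prior volume
plus a handful of golden-angle radial k-space spokes of the current
anatomy, by solving a patient-specific deformable registration problem
with an implicit neural representation (INR) that can be meta-learned
across a cohort.  This note records the model, the numerical conventions,
the synthetic study conditions, and the design choices that were open.

## Problem setting and model

A case consists of a fully-sampled complex source volume `S_FI` (the
prior anatomy, e.g. the 0% respiratory bin) and undersampled radial
k-space samples `T_UK` of the target anatomy.  The estimate is a warped
prior: a displacement field `d(v)` (backward convention, target
coordinates into the source) is applied through a trilinear spatial
transformation layer, and the warped volume's non-uniform Fourier samples
are compared to the measured `T_UK`.

The displacement field is the output of a SIREN coordinate network

    F0  = sin(omega0 (w_i v + b_i))
    F_l = sin(gamma_l (w_l F_{l-1}) + beta_l b_l),  l = 1..3
    d   = w_o F3 + b_o

with coordinates normalised to [-1,1]^3 and displacements in
full-resolution voxel units.  Only the three hidden layers are modulated;
note the coefficients `beta_l` *scale the bias* rather than adding a
FiLM-style shift (a FiLM variant exists behind a flag for ablation).  The
modulation coefficients come from a token-aware modulator: non-overlapping
3D patches of the six-plane input `X = (Re/Im S_FI, Re/Im S_UI, Re/Im
T_UI)` are embedded as tokens, passed through one transformer encoder
block, attended by a second multi-head attention layer, mean-pooled, and
mapped by three two-layer generators to `(gamma_l, beta_l) = (1 + delta)`.
The generators' final layers are zero-initialised so the modulation is
exactly the identity before training — meta-training starts from the
unmodulated template, the stable choice where no initialisation is
prescribed.

`S_UI` and `T_UI` are adjoint ("inverse NUFFT") reconstructions of the
source projected through the *target's* trajectory and of the target
samples, so both carry matched streak artifacts.

## k-space simulation

Sampling is stack-of-stars: one 2D golden-angle radial trajectory
(increment exactly 111.25°, random initial azimuth per acquisition)
applied to every axial slice.  Spokes span the full diameter with radii
`linspace(-pi, pi, n, endpoint=False)` (the duplicate +pi edge sample is
excluded by default; a flag includes it).  The forward operator is the
direct type-3 NUDFT evaluated through an explicit sample-by-pixel matrix
with the zero-frequency reference at voxel `floor(N/2)`; the same real
matrices back the differentiable operator inside the losses, so there is
no oracle/implementation split to maintain.  The adjoint divides by the
per-slice sample count, keeping magnitudes comparable across spoke
counts.  No density compensation is applied anywhere: the adjoint images
are deliberately artifact-bearing network inputs, not reconstructions.
Consequently the adjoint carries a fixed `1/|k|`-type blur whose error
does not vanish with spoke count; undersampling quality comparisons are
therefore made against a densely-sampled adjoint reference.

The acceleration factor is `(pi/2 * matrix) / n_spokes` (radial Nyquist
spoke count over acquired spokes); for a 256 matrix, 13/9/5 spokes give
approximately 31/45/80.

## Losses and the two-step scheme

* Step A (deformation discrepancy): sum over x,y,z of the mean absolute
  difference between the INR's upsampled field and the frozen prior
  net's reference field.
* k-space fidelity: mean squared complex modulus of the residual between
  the warped source's NUDFT samples and `T_UK`, over all `N_k` samples.
* Embedding similarity: mean cosine similarity between bottleneck
  embedding vectors of the warped source and of `T_UI`, extracted by the
  frozen prior encoder.  The literal printed form of this loss would
  *reduce* similarity when minimised; the package negates it by default
  (flag for the literal form), since the term exists to encourage
  alignment.
* Smoothness: mean deformation energy — squared forward differences per
  axis in voxel units, replicate boundary (last difference zero).

Step B minimises `lambda1 * kspace + lambda2 * embed + lambda3 * smooth`
with defaults (1.0, 0.5, 0.5).

The embedding encoder expects six planes but receives 2-plane complex
volumes; the real/imag pair is tiled three times (the documented adapter
— the frozen encoder is reused without retraining).  Embeddings are taken
at the bottleneck (deepest level), the conventional latent; multi-level
embeddings sit behind a flag.

## Prior network

A small UNet-style encoder-decoder (6 input planes, 3 output planes,
one down-sampling level, base width 8 at desk scale) with a tiny-variance
flow head so the untrained network predicts near-zero motion.  It is
trained unsupervised across subjects on random bin pairs with random
trajectories, minimising `kspace + 0.5 * smooth`; afterwards it is frozen
— meta-training and adaptation only read its DVFs and embeddings, and
tests pin its parameter checksum.

## Meta-training and adaptation

Per outer iteration and subject: draw a random (source, target) bin pair
and trajectory; compute the modulation with the *frozen* modulator; load
the template `Phi`; run `n_inner` step-A epochs then `n_inner` step-B
epochs (one full-batch gradient step per epoch); accumulate the Reptile
delta `(Phi'' - Phi) / N_x`; then update the modulator once by
backpropagating the step-B loss through the modulation with the INR
frozen at `Phi''`.  After all subjects, `Phi <- Phi + delta`.  Adam state
is re-created per subject and reset between step A and step B, keeping
inner loops independent and the Reptile semantics clean.  Test-time
adaptation repeats the A-then-B schedule (`n_adapt` epochs each) from the
meta-learned template under the case's own modulation; it consumes no
ground truth.

Run modes: `cmeta` (full), `meta_inr_b` (no embedding loss), `meta_inr_a`
(additionally no prior guidance), `meta_inr` (CNN-encoder modulation,
no attention), `ks_inr` (random-init INR, k-space + smoothness only),
`ks_iterative` (voxelwise DVF array on the coarse grid through the same
upsampling path, no network).

## Parameters that matter

| parameter | default | note |
|---|---|---|
| INR widths | (3, 256, 256, 256, 3) | hidden width 64 at desk scale |
| omega0 | 30 | standard SIREN frequency scale |
| coordinate downsample | 2 per axis | DVF predicted coarse, upsampled trilinearly |
| token dim / heads | 192 / 4 | 48 / 4 at desk scale |
| modulation dim | hidden width | one (gamma, beta) pair per hidden layer |
| lambda1, lambda2, lambda3 | 1.0, 0.5, 0.5 | step-B weights |
| n_outer / n_inner / n_adapt | 500 / 10 / 50 | desk studies use 15-25 / 10 / 10-100 |
| lr | 1e-5 | published schedule; desk studies use 5e-3 (see below) |
| spokes | 13 (range 5-50 in training) | 256 samples/spoke; 32-64 at desk scale |

The published learning rate 1e-5 pairs with very long schedules on GPU
hardware; at desk problem sizes the same Adam optimiser with 5e-3 and
100-200 steps reaches the corresponding optima.  This is a problem-size
choice, recorded here once and used consistently by all studies.

## Synthetic study conditions

The generator emulates the phase-augmentation recipe for magnitude-only
4D-MRI: ellipsoid phantoms (optionally edge-smoothed and textured) for
anatomy; phase maps as sums of four sinusoids per Cartesian axis with
frequencies uniform in 1.25e-3 to 2.5e-3 per mm (wavelengths 800-400 mm)
and random phase shifts; complex volumes `magnitude * exp(i phase)`;
zero-mean Gaussian noise with sd drawn from 3e-3 to 5e-3 added
independently to real and imaginary planes.  Motion is an analytic
surrogate — separable Gaussian envelope times `sin(pi * bin fraction)`,
dominant along the slice axis — because parameter-recovery tests need
exactly known ground truth; phase maps and structure masks are warped
with the same fields as the magnitude (masks by nearest neighbour, to
preserve binarity).  Bin 0 is always the motion-free reference.

What the phantoms do *not* model: coil arrays, B0 inhomogeneity,
relaxation or sequence physics, through-plane anatomy changes, sliding
interfaces, or intensity non-stationarity between bins.  Passing tests
demonstrate that the estimator recovers known smooth deformations from
severely undersampled simulated data; they do not establish clinical
accuracy on real acquisitions.

## Desk-scale studies

* Recovery: one 32x32x8 subject, 13 spokes x 64 samples, `ks_inr`, 100
  adaptation epochs; scores relative error and Dice against the known
  clean target, plus a zero-motion control (60 epochs).
* Meta advantage: 16x16x8, three sub-seeds; per sub-seed a 6-subject
  cohort meta-trains a token-modulated template (25 outer iterations, no
  prior, isolating the initialisation) and 5 held-out subjects measure
  step-B epochs until the k-space loss falls below 10% of its
  zero-displacement value (cap 150).  Medians pool all 15 pairs.
* Ablation ladder: 16x16x8, four sub-seeds of 12 subjects (6 train, 6
  held out x 3 bins); a 200-epoch prior; 15 outer iterations per variant;
  deliberately short 10-epoch adaptation so the initialisation quality,
  not per-case optimisation, dominates; Dice pooled over all 72 cases.
  The component effects are small relative to per-case spread (they are
  small in the full-scale setting too), which is why the study pools
  cases — and the cohort/prior/meta-training noise — across sub-seeds
  before taking medians.

## Numerical conventions and degenerate inputs

Trilinear warping uses border clamping; displacement gradients vanish on
clamped samples.  DVF upsampling is separable align-corners linear
interpolation (reproduces linear fields exactly; no value rescaling since
displacements are stored in full-resolution voxel units).  Dice of two
empty masks is defined as 1 with a warning; HD95/COME reject empty masks.
HD95 uses 6-connectivity boundary voxels, physical-space KD-tree
distances, numpy linear-interpolation percentiles, and the maximum of the
two directed 95th percentiles.  SSIM is the global single-window form on
[0,1]-scaled magnitudes with c1 = 1e-4, c2 = 9e-4.  Zero-norm embedding
vectors contribute zero cosine with a warning.  All randomness flows from
one seed through a CRC-32-labelled `SeedSequence` splitter, so every
stage is reproducible in isolation; training is full-batch, hence
bit-reproducible on CPU.

## Known limitations

The differentiable stack is a purpose-built numpy autodiff engine —
adequate and exhaustively gradient-checked at these problem sizes, but
not performant at the published 256x256x32 scale.  The transformer
encoder is a single standard block over patch tokens, reproducing the
role (tokens -> attention -> coefficients) of a windowed/shifted design,
not its internals.  The adjoint reconstruction is uncompensated by
design.  The motion surrogate is diffeomorphic-by-construction and
smooth; performance on sliding or discontinuous motion is out of scope.
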