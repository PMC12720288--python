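# cminr

Registration-driven volumetric MRI estimation from severely undersampled
golden-angle radial k-space data, using cohort-informed meta-learned
implicit neural representations.

## The problem

Real-time volumetric MR guidance (for example on MR-LINAC platforms)
cannot wait for fully-sampled acquisitions: only a few radial k-space
spokes of the current anatomy are available at any instant.  Rather than
reconstructing an image from so little data, this package estimates the
current volume by *deforming a fully-sampled prior volume* of the same
patient until its simulated radial samples agree with the measured ones.
The estimator is a SIREN coordinate network `INR(v; Phi, gamma, beta)`
mapping normalised voxel coordinates `v` to a displacement field
`d(v)`; the deformed prior is `S_DI(v) = S_FI(v + d(v))`, and the
data-fidelity loss lives in k-space:

    L_kspace = (1/N_k) * sum_i | NUDFT(S_DI)(k_i) - T_UK(k_i) |^2

augmented by a deformation-discrepancy term against a population prior
network's reference DVF (step A), an embedding cosine-similarity term
(from the frozen prior's encoder), and a deformation-energy smoothness
penalty, combined as `lambda1 L_kspace + lambda2 L_embed + lambda3
L_smooth` with (1.0, 0.5, 0.5).  A Reptile-style outer loop meta-learns
the template `Phi` across a cohort while a token-aware modulator
(patch tokens, transformer block, attention pooling, per-layer
coefficient generators) conditions the three hidden layers per case, so
test-time adaptation needs only a few optimisation epochs.  Everything
runs on CPU at configurable grid sizes with exactly-known synthetic
ground truth.

The package is for researchers in MR-guided adaptive imaging who want a
fully-inspectable, deterministic implementation of this estimation
pipeline — including the radial NUDFT simulation, the losses, the
ablation/baseline run modes, and the evaluation metrics (global SSIM,
relative error, Dice, HD95, centre-of-mass error).

## Worked example

`examples/03_register_from_scratch.py` builds a 32x32x8 motion-resolved
phantom subject, takes 13 golden-angle spokes of the moving bin
(acceleration factor ≈ 31 at a 256 matrix, ≈ 4 at this grid), and fits
an INR from scratch on the k-space fidelity and smoothness losses:

```text
unregistered relative error : 73.3 %
registered relative error   : 2.0 %
error reduction             : 97 %
structure Dice              : 0.639 -> 0.995
SSIM after registration     : 1.000
zero-motion control, mean |d|: 8.18e-05 vox
```

The warped prior recovers the target to 2% intensity error from 13
spokes; structure overlap becomes near-perfect; and on a motion-free
control the solver stays at the identity transform (mean displacement
~1e-4 voxels), i.e. it does not hallucinate motion.  The other examples
cover cohort simulation, the radial k-space pipeline, prior-net
training, the meta-learning speed-up, and the end-to-end config-driven
pipeline (also available as the `cminr` CLI with `simulate`,
`train-prior`, `meta-train`, `adapt`, `evaluate` and `pipeline`
subcommands).

## Library map

| module | contents |
|---|---|
| `cminr.synthetic` | phantom cohorts: sinusoidal phase maps, analytic motion, complex noise |
| `cminr.kspace` | golden-angle trajectories, direct NUDFT forward/adjoint, preprocessing |
| `cminr.inr` | SIREN template, token/CNN modulators, coordinate grids |
| `cminr.prior` | lite UNet population prior: DVFs, embeddings, cohort training |
| `cminr.warp` | trilinear DVF upsampling and spatial transformation |
| `cminr.losses` | step-A discrepancy, k-space MSE, embedding cosine, smoothness |
| `cminr.meta` | Reptile meta-training, test-time adaptation, variant run modes |
| `cminr.metrics` | SSIM, RE, Dice, HD95, COME |
| `cminr.experiments` | the three reproducible desk-scale studies |
| `cminr.config` / `cminr.cli` | YAML run configs, seed fan-out, subcommands |

## Method docs

See `docs/methods.md` for the model, numerical conventions, study
conditions, and limitations.
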