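# Methods

## Problem and pipeline

The package identifies infarcted myocardium in the left ventricle (LV)
from cardiac strain alone.  Its pipeline mirrors a strain-based infarct
segmentation study end to end at desk scale: circumferential, radial and
longitudinal (CRL) end-systolic Green–Lagrange strains at four short-axis
levels (base, mid, apical, apex) are painted onto AHA bullseye discs,
normalized into a 3-channel image, and segmented by encoder–decoder
networks into per-pixel infarct probabilities.  A composite multi-fidelity
network transfers a model trained on abundant clean ("low-fidelity",
simulation-like) data to a noisier ("high-fidelity", human-CMR-like)
domain using a single high-fidelity example.

## Synthetic strain library

The generator is a phenomenological stand-in for a library of forward
finite-element simulations of infarcted hearts.  It does not solve any
mechanics; it reproduces the statistical structure the networks must
learn.

Geometry is a polar grid of 4 levels × 64 angular bins, each cell treated
as equal wall area.  Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_examples` | 592 | library size |
| `n_base_models` | 4 | base hearts (amplitude scales 1.0/0.95/0.9/0.85, emulating 1–4 weeks after infarction) |
| `size_bounds` | (0.05, 0.60) | infarct fraction of LV wall area, LHS-sampled |
| `stiffness_bounds` | (0.7, 1.3) | per-region stiffness multiplier, LHS-sampled |
| `healthy_cc` | −0.11…−0.14 | healthy end-systolic E_CC per level (dimensionless) |
| `healthy_rr` | +0.24…+0.30 | healthy E_RR (wall thickening) |
| `healthy_ll` | −0.13…−0.16 | healthy E_LL |
| `severity_intercept/slope` | 0.55 / 0.40 | attenuation s = s0 + s1·(m−0.7)/0.6 |
| `border_zone_width` | 0.12 rad | sigmoid width of the border zone |
| `noise_amplitude` | 0.015 | correlated noise std (correlation 2 bins) |
| `hf_smooth_sigma` | 2.0 bins | high-fidelity smoothing |
| `hf_amplitude_bias` | 0.85 | high-fidelity amplitude shrinkage |
| `hf_noise_amplitude` | 0.025 | extra high-fidelity noise |

Healthy baselines are in the range of reported human end-systolic LV
strains (circumferential and longitudinal shortening around −0.10 to
−0.20, radial thickening around +0.25), with magnitudes growing slightly
toward the apex.  Infarct size and stiffness are Latin-hypercube sampled
so every one of the n strata of each dimension holds exactly one sample;
infarct centers are uniform over levels × angle.  The infarct is grown
from its center cell by geodesic distance (angular distance combined with
an inter-level spacing of 0.5 rad) until the target area is reached, which
keeps the region contiguous and makes the realized mask fraction track the
sampled one to well within 10 % relative error.  Inside the region every
strain component is attenuated toward zero by the severity s — stiffer
(higher multiplier) infarcts contract less — through a sigmoid border
zone; an optional positive E_CC "bulge" (dyskinesis) is available but off
by default so that severity is strictly monotone.  All randomness flows
from explicit integer seeds; examples are bit-reproducible.

What the generator deliberately does **not** emulate: mesh-based LV
geometry, pressure–volume-consistent mechanics, through-plane strain
coupling, per-patient anatomy, or imaging artifacts beyond smoothing and
stationary correlated noise.  Passing tests therefore demonstrate that
the pipeline learns depressed-strain regions under these statistics, not
clinical performance on human scans.

## Bullseye preprocessing

Ring boundaries sit at 0.25/0.50/0.75/1.00 of the disc radius with the
apex innermost and the base as the outer ring; angle zero lies on the
image +x axis, increasing counterclockwise.  Continuous angular profiles
are rendered per ring (a 17-segment averaging mode is intentionally not
the default, since strain fields are spatially continuous).  Strain maps
to intensity by a fixed affine map per component whose range is derived
from the generator's healthy baselines padded by six noise standard
deviations — dataset-independent, so both fidelity domains share one
mapping and intensities stay strictly inside [0, 1].  Channels are stacked
R = circumferential, G = radial, B = longitudinal; background pixels are
exactly zero.  Augmentation is the fixed rotation set 90°/180°/270°
(fourfold increase); splits are grouped by source example so rotated
copies never straddle train/validation/test.

## Networks

All four architectures share the contract: (H, W, 3) in [0, 1] in,
per-pixel probability out through a final 1×1 convolution and sigmoid.
The base UNet follows the published table: five levels of two 3×3
convolutions + ReLU with channel widths 16, 32, 64, 128, 256, 2×2 max
pooling down, biased 2×2 stride-2 transposed convolutions with skip
concatenation up, and no batch normalization — exactly 1,941,105
trainable parameters.  The variants are documented constants where the
source under-specifies internals: attention gates use additive attention
with an intermediate width of half the skip channels, gated by the
coarser decoder feature upsampled to the skip resolution; dense encoder
blocks use two growth layers (growth = level width, conv → BN → ReLU)
with concatenative connectivity closed by a 1×1 transition; residual
blocks are pre-activation with a three-convolution branch and an
identity/1×1 shortcut, so zeroing the final convolution reduces a block
to its shortcut.  Parameter counts order
UNet < attention < dense < residual-attention
(1.94 M < 1.97 M < 2.55 M < 2.80 M); the variants' exact published counts
are not reproduced because their internals are not recoverable, only the
ordering is asserted.

The networks run on the package's numpy autodiff backend (reverse-mode,
float32, im2col convolutions recomputed in the backward pass to bound
memory).  Gradients of every primitive and of all four architectures are
verified against central finite differences in float64.  Weights are
initialized fan-in uniform from a seeded generator; training uses Adam.

## Losses, metrics and conventions

BCE clips probabilities to [1e−7, 1−1e−7]; the soft Dice loss uses the
squared denominator 1 − 2Σpy/(Σp²+Σy²) and the soft IoU loss
1 − Σpy/Σ(p+y−py), each with an additive smoothing constant of 1e−6 so
empty masks are defined.  Evaluation metrics come from pixel confusion
counts; two empty masks score 1.0 for both IoU and DSC.  Binarization
threshold is 0.5 (the sigmoid midpoint).

## Multi-fidelity composite network

y_H = F_l(x_H, y_L) + F_nl(x_H, y_L), where y_L is the low-fidelity
UNet's output on the high-fidelity image and both correction networks
consume the 4-channel stack (x_H ‖ y_L).  F_l is a single 10×10
convolution with no activation; F_nl the same kernel followed by a leaky
ReLU (slope 0.01).  The even kernels are padded asymmetrically (4 before,
5 after) to preserve spatial size.  All three networks are trained
jointly — the loss MSE_L + MSE_H + λΣβ² (λ = 1e−4, β over the weights of
both branches, MSE terms as per-pixel means so the two fidelity terms are
scale-comparable) couples them, and joint end-to-end minimization is the
simplest faithful reading of a single summed objective.  The
high-fidelity training set is one example plus its three fixed rotations
(N_H = 4); the held-out high-fidelity example is never seen, and an
explicit guard raises if the training and held-out examples coincide.
The raw sum y_H is unbounded, so it is clipped to [0, 1] before
thresholding at 0.5.

## Constitutive model and strain kinematics

Total Cauchy stress: T = (1/J)·F̄·(∂W_dev/∂Ē)·F̄ᵀ + (∂W_vol/∂J)·I +
(1/J)·F·S_act·Fᵀ, implemented literally as this additive split with the
volumetric pressure entering as (∂W_vol/∂J)·I.  ∂W_dev/∂Ē is analytic
(c·e^Q times the symmetric-tensor gradient of the quadratic Q, rotated
from the fiber frame) and is verified against central finite differences
of the energy (step 1e−6, relative error ≤ 1e−5 over 100 random
deformations with det F ∈ [0.8, 1.2]) rather than trusted as hand
algebra.  W_vol = (K/2)((J²−1)/2 − ln J) is non-negative with its unique
minimum at J = 1.  The active law Ta = T_Ca[1+β(√(2E_f+1)−1)] is affine
in the fiber stretch, non-decreasing for β ≥ 0, and zero in infarcted
tissue (T_Ca = 0).  Units are kPa throughout.

Kinematics: spatial derivatives use central differences in the interior
and first-order one-sided stencils at borders — exact for affine
displacement fields, which anchors the tests.  Increment composition is
left-multiplication by later increments (composition of motions reads
right to left).  2-D slices are treated as 3-D with zero through-plane
displacement.  The CRL frame takes radial as the in-plane unit vector
away from the LV centroid, circumferential 90° counterclockwise in-plane,
longitudinal as the slice normal, with the rotation's rows ordered
(circ, rad, long) so the transformed diagonal reads E_CC, E_RR, E_LL.

## Desk-scale protocols

Full training defaults are 100 epochs, early-stopping patience 5
(monitoring validation loss and restoring the best checkpoint), batch
size 128, image size 128, Adam at learning rate 1e−3.  The tests and the
acceptance script run reduced protocols chosen so every comparison keeps
its structure on a single CPU core:

* image sizes 128/256/512: base channels 4, depth 5, 8 source hearts
  (32 augmented images), 10 epochs, batch 2, lr 3e−3;
* losses and architectures: 64 px, base channels 8, depth 4, 24 source
  hearts, 16–24 epochs, batch 16, lr 3e−3;
* multi-fidelity: 32 px, base channels 8, depth 4; the composite network
  trains jointly for 30–40 epochs at batch 8, the single-fidelity
  baseline for 12 epochs; evaluation follows the swap protocol on two
  held-out high-fidelity hearts.

At these scales the UNet reaches test DSC ≈ 0.89–0.97 on the synthetic
library, and the multi-fidelity model reaches held-out DSC ≈ 0.8 on the
shifted domain where the single-fidelity baseline is unstable (its
probabilities often fall below threshold wholesale under the amplitude
bias) — the same qualitative ordering the full-scale study reports.

## Numerical choices and known limitations

* float32 forward/backward; gradient checks run in float64.
* Maxpool ties resolve to the first maximum; nearest-neighbour upsampling
  is used to resample attention maps.
* The sigmoid is evaluated piecewise to avoid overflow.
* Empty-vs-empty mask metrics return 1.0; probability clipping bounds the
  BCE at −ln(1e−7).
* The generator's severity mapping is linear in the stiffness multiplier;
  real infarct mechanics are nonlinear and time-dependent.
* Image registration (producing the displacement fields consumed by the
  kinematics module) is out of scope; displacements are inputs.
* No claim of biomechanical fidelity: the library stands in for
  finite-element solutions statistically, not mechanically.
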