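# Methods

## Scene model

A scene is `N` anisotropic 3D Gaussians. Raw (stored) parameters are
unconstrained so first-order optimizers can update them freely; the
activated parameters live on their natural domains:

| parameter    | storage          | activation      | domain      |
|--------------|------------------|-----------------|-------------|
| mean μ       | 3-vector         | —               | ℝ³ (scene units) |
| rotation r   | quaternion (w,x,y,z) | normalize   | unit quaternions |
| scales s     | log-scales       | exp             | (0, ∞)³, std devs |
| opacity σ    | logit            | sigmoid         | (0, 1)      |
| color        | SH coefficients  | —               | ℝ^(K×3), K = (L+1)² |

The opacity sigmoid is the standard choice; for the scale parameter we
use log-storage with `exp` (rather than a sigmoid) because it
guarantees positivity without bounding the scale above, matching common
splatting practice. The covariance is `A = R S Sᵀ Rᵀ`, so its
eigenvalues are exactly the squared activated scales.

View-dependent color uses the real orthonormal spherical-harmonic basis
up to degree 3 in the ecosystem's component convention; the degree-0
term is mapped to RGB as `0.282095·c₀ + 0.5` (mid-gray offset,
switchable off via `GaussianCloud.sh_offset`), and the result is
clamped at zero. The default degree for the synthetic fixtures is 1,
keeping the parameter count small at desk scale.

Quaternions are (w, x, y, z) everywhere, matching the COLMAP text
format the package reads; cameras use the COLMAP/OpenCV convention
(x right, y down, z forward; pixel (i, j) has center (j+0.5, i+0.5);
poses stored world-to-camera).

## Projection and the adaptive low-pass filter

A Gaussian with camera-space mean t = (x, y, z) is projected with the
local affine approximation of the perspective map: the 2×3 Jacobian

    J = [ fx/z   0     −fx·x/z² ]
        [ 0      fy/z  −fy·y/z² ]

so the screen-space covariance is `A″ = (J W) A (J W)ᵀ` (equivalently
the upper-left 2×2 block of the 3×3 product with the full Jacobian;
rows beyond the second never enter). Gaussians at or behind the near
plane are culled, as are those whose projected mean lies outside the
image rectangle expanded by the splat's 3σ screen extent.

The default near plane is deliberately generous (`znear = 0.2` scene
units, the reference-rasterizer convention) rather than epsilon-small.
The affine approximation is only trustworthy near the splat's mean: a
splat lying far off-axis at tiny forward depth is many standard
deviations outside that neighborhood, the −f·x/z² Jacobian entries
explode, and the extrapolated footprint paints a phantom near-uniform
veil across the entire frame — which then pops on and off as the mean
crosses the near plane between nearby camera poses. Culling at z < 0.2
removes the regime in which the approximation is invalid; with the
synthetic tube fixtures this changes adjacent-frame brightness jitter
from ~0.13 to ~0.006 in mean pixel value.

The adaptive low-pass filter replaces `A″` by `A″ + sI` and multiplies
the splat by the energy prefactor `det(A″)/det(A″+sI)`. `s` is
specified in squared pixels (default 0.3), so the world-space smoothing
it induces shrinks as resolution grows — that screen-space anchoring is
what makes the filter adapt to the sampling rate. Two prefactor
normalizations are provided:

* `prefactor_mode="linear"` (default): the determinant ratio itself.
* `prefactor_mode="sqrt"`: the square root of the ratio. This is the
  energy-preserving choice — the total integrated energy of a 2D
  Gaussian scales with √det, so the square-root ratio leaves each
  splat's integrated contribution unchanged while spreading it.

Measurement on the aliasing-stress fixture (below) shows the linear
prefactor over-attenuates sub-pixel splats — quadratic rather than
linear energy loss — and *increases* error at 1/8 resolution, while the
sqrt variant reduces it severalfold. The multi-resolution experiments
therefore run with `prefactor_mode="sqrt"`; the linear form remains the
default for fidelity to the filter's published definition.

## Rasterization

Splats are depth-sorted globally per frame (camera-space z, ties broken
by Gaussian index — deterministic), binned into 16×16-pixel tiles by
their axis-aligned 3σ squares, and composited front to back per pixel:

    αᵢ = min(0.99, σᵢ · prefactorᵢ · exp(−½ Δᵀ (A″+sI)⁻¹ Δ)),

with transmittance `T` starting at 1 and multiplying by (1−αᵢ);
accumulation stops once `T < 1e-4` and the remainder is composited over
the background (default black — endoscopy frames have dark vignettes,
so black is the least-harm choice). The Mahalanobis form uses the
*inverse* of the filtered covariance (standard EWA splatting).

**Kernel truncation.** A splat contributes only within Mahalanobis
radius 3 of its 2D mean (exponent cutoff 4.5). This truncation is part
of the splat model, applied identically in the tiled renderer and the
brute-force oracle; it is what makes the two paths agree to rounding
error, since the 3σ binning extent would otherwise silently truncate
the tiled path only (a tail crossing into an unbinned tile is as large
as e^(−4.5) ≈ 0.011). The closed-form single-splat oracle and the
moment-recovery test account for it analytically (an elliptically
3σ-truncated Gaussian's principal second moments shrink by the factor
1 − 4.5·e^(−4.5)/(1−e^(−4.5)) ≈ 0.9495).

**Oracles.** `render_bruteforce` is the same contract with a per-pixel
global loop — no tiling, no early termination. The two agree to < 1e-5
(in practice bit-exactly) on scenes where transmittance never crosses
the 1e-4 early-termination threshold; on deep-stack scenes the
difference is bounded by that threshold, which is the documented scope
of the equivalence property. `render_supersampled_reference` renders at
K× resolution without the filter and box-downsamples — the alias-free
reference for the anti-aliasing experiments (and the generator of
synthetic ground truth, K = 4, so training targets are independent of
the filter under test).

## Gradients

No autodiff framework is used: the backward pass is hand-derived and
verified against central finite differences (relative error < 1e-3,
typically ~1e-7) for every parameter group. The chain runs: per-pixel
blending (back-to-front traversal dividing out (1−α), exact for the
forward pass including the α cap and early stop) → conic, prefactor and
determinant algebra on 2×2 covariances (adjugate form, stable near
singular `A″`) → the EWA products `A″ = (J W R S)(J W R S)ᵀ` → the
Jacobian's own dependence on the camera-space mean → activations and
the quaternion normalization → the spherical-harmonic basis derivatives
with respect to the viewing direction (so moving a Gaussian correctly
changes its view-dependent color). The SSIM term of the loss is
likewise differentiable in closed form (windowed-statistics chain rule,
adjoint filtering), checked against finite differences and, for the
value, against scikit-image to machine precision.

SSIM uses the universal defaults — 11×11 Gaussian window, σ = 1.5,
k₁ = 0.01, k₂ = 0.03, MAX_I = 1 — averaged over the interior region
where the window fits entirely, making the value independent of any
boundary convention. PSNR is `20·log₁₀(MAX_I/√MSE)` dB; identical
images report `inf`.

## Training

Per iteration, one training view is rendered and
`L = (1−λ)·L1 + λ·(1−SSIM)` backpropagated; λ = 0.2. Updates are
adaptive-moment (Adam-style, β = 0.9/0.999, ε = 1e-15) per parameter
group with rates: means 1e-4, opacity 0.05, log-scales 5e-3, rotations
1e-3, SH 2.5e-3 (all configurable; plain SGD via
`optimizer="sgd"` — the scale-invariant Adam steps jitter at an exact
fixed point, SGD preserves it). Views are visited in seeded random
permutations, so a run is a pure function of its seed.

Adaptive density control runs every 100 iterations between iteration
500 and half the run. Gaussians whose mean accumulated screen-space
(NDC) positional-gradient norm exceeds τ_pos = 2e-4 are densified:
cloned (duplicated with a small offset of 0.1 × mean scale along the
accumulated gradient direction) when their largest scale is below 1% of
the scene extent, otherwise split into two children sampled from the
parent with scales divided by 1.6. The resulting cloud is then pruned:
activated opacity below ε_α = 0.005, or largest scale above 10% of the
scene extent. The size prune matters for view interpolation: without
it, a single Gaussian can grow into a whole-frame "floater" that fits
the training views but pops in and out (its mean crossing the
near-plane cull) at in-between poses, leaving a uniform image-wide
error on held-out views. Densification stops adding Gaussians once the
cloud reaches `max_gaussians` (default 3000, the desk-scale budget;
pruning continues), keeping per-iteration cost bounded. The count
change per control step is exactly `clones + splits − pruned`. An
opacity-reset feature (clamp to ≤ 0.01 every 3000 iterations) is
included and on by default, though desk-scale runs (≤ 2000 iterations)
never reach it.

## Synthetic fixtures

The generator emulates the statistical structure of nasal-endoscopy
footage at desk scale: a curved tube (cubic-spline centerline, radius
0.5 scene units) whose inner surface carries surface-aligned anisotropic
Gaussians (tangential footprint ~0.7·√(surface area / N), normal scale
15% of that, ±3% radial jitter), colored by a band-limited sum of 3D
sinusoids mapped to a reddish tissue-like palette; a camera flies along
the centerline looking forward with temporally smooth pose jitter
(consecutive rotations differ by well under 10°). Defaults: 2000
Gaussians, 256×144 frames (the 16:9 clinical aspect at desk scale), 100
frames split 90/10 with test frames held out evenly along the
trajectory. Ground truth is rendered from the known cloud with 4×
supersampling and no filter. Everything is a pure function of
(spec, seed).

What this does *not* emulate — and hence what passing tests do not
establish about clinical data: tissue deformation, specular wet-surface
highlights, instrument occlusion, illumination falloff from the
endoscope's own light source, rolling-shutter or compression artifacts,
and SfM pose error (poses here are exact by construction).

Two derived conditions:

* **Recovery experiment** — the ground-truth cloud is perturbed (means
  by 0.05 scene units ≈ one tangential footprint; log-scales by 0.3;
  opacity logits by 1.0; DC color by 0.2; quaternions by 0.1) and
  retrained for 2000 iterations. The perturbation is sized to corrupt
  the render visibly (initial training loss several times the
  reconstruction floor) while leaving recovery well-posed; held-out
  PSNR ≥ 25 dB / SSIM ≥ 0.85 and a better-than-halved training loss are
  the pass conditions. Runs in ~2-3 minutes per seed on one CPU core.
* **Aliasing-stress fixture** — 4000 Gaussians with footprints shrunk
  3.3× (`scale_multiplier = 0.3`) and a high-frequency color field, so
  splats are sub-pixel at 1/8 resolution. A high-frequency color field
  alone cannot produce splatting aliasing while footprints stay
  multi-pixel; the footprint shrink is what creates the regime the
  filter exists for.

## Degenerate inputs and numerical choices

Empty clouds render as pure background with transmittance 1. Splats
with non-positive-definite filtered covariance are skipped with a
warning. Zero-norm quaternions, non-positive scales, negative filter
scales, shape-mismatched images and zero-size cameras raise
`InvalidParameterError`. Determinant gradients use adjugates (finite
even when `A″` is singular). All rendering math is float64; renders are
bitwise deterministic for fixed inputs. PLY checkpoints store raw
parameters as float32 by default (the splat-viewer convention; a
float64 mode preserves exact round trips); COLMAP text files use
`repr` formatting, so text round trips are lossless to float64.

## Known limitations

CPU-only (Numba kernels, single-threaded); desk-scale by design —
40k-iteration, megapixel-scale runs are supported in principle but not
exercised. The deblurring stage is an interface with classical
reference implementations (identity, unsharp mask, Wiener); the heavy
pretrained diffusion deblurrer used clinically is intentionally out of
scope and plugs in through the same interface, as does any learned
perceptual (LPIPS-style) metric backend. Per-pixel ordering is the
global per-frame depth sort, not an exact per-pixel visibility sort.
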