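# Methods

This note documents the model, the numerical choices and the synthetic
study conditions behind `endovo`, and what the passing tests do and do
not demonstrate.

## Pose model

The relative camera pose between consecutive stereo frames is
parameterized as a twist `p = (v, w) ∈ se(3)`, translation first,
rotation (axis-angle, radians) second. Depth maps are divided by the
maximum expected depth before any residual is formed, so translation
components are dimensionless and commensurate with rotations — this
conditions the 6-D optimization. `p_t` maps frame-*t* camera
coordinates into frame *t−1* ("aligns view t onto view t−1"); with
camera-to-world poses `C_t` this means `exp(p_t) = C_{t−1}⁻¹ C_t` and
trajectories chain as `C_t = C_{t−1} · exp(p_t)`. A dedicated test pins
this convention.

Two per-pixel residuals are combined:

* the 2-D flow-reprojection residual, with the x/y error components
  divided by the image width/height so values are resolution-free;
* the 3-D point-to-point residual against the previous point cloud
  bilinearly warped to the flow target.

The objective is the sum over valid pixels of the *squared weighted sum*
`(ω_2D r_2D + ω_3D r_3D)²` — the cross term is kept. Both residuals are
`sqrt(‖e‖² + ε²)` with ε = 1e-8 (normalized units, ≈1 µm at 100 mm):
the objective is then twice differentiable everywhere, which implicit
differentiation requires. ε was chosen to balance two numerical floors:
the smoothing contributes ≲2e-12 to the objective of a perfect solution
(far below every bound we verify), while the cross-term curvature —
which grows as 1/ε at zero residual — stays bounded enough for the
solver to reach stationarity in float64.

**Valid set Ω.** Pixels are dropped (contributing exactly zero,
gradient included) when depth or flow is invalid, the normalized depth
exceeds 1, the flow target leaves the image or lands on invalid
previous-frame pixels, or they are covered by the instrument mask or
the specularity mask (maximum-channel intensity ≥ 0.98, dilated 2 px).
Ω is frozen per solve so the objective stays smooth; it is re-derived
for each frame pair.

## Solver

L-BFGS (scipy, history 10, strong-Wolfe line search) with exact
first-order forward-mode gradients, followed by up to 8 damped Newton
steps using the exact 6×6 Hessian. The polish exists because L-BFGS
stops on objective decrease and near flat minima can leave the gradient
around 1e-2; the implicit-gradient layer needs a genuine stationary
point (∞-norm ≤ 1e-6). Newton steps are accepted only if they shrink
the gradient without increasing the objective, with Levenberg damping
λ ∈ {0, 1e-12, …, 1} and backtracking down to 1/100 of the step.

Derivatives come from a small forward-mode automatic-differentiation
kernel (dual numbers with 6 tangent lanes, optionally 6×6 second-order
lanes). With only six parameters, forward mode gives exact gradients
and Hessians in a handful of vectorized array operations — no graph
framework needed, and the Hessian is exact rather than Gauss-Newton.

*Known corner:* when a solve lands on the ε-floor (objective ~1e-9,
noiseless data), third derivatives of the cross term (~1/ε²) make
strict stationarity ill-conditioned; the solver may report
`converged=False` at |g|≈1e-3 while the pose is accurate to ~1e-7.
Training is unaffected (its objective floors are orders larger).

Ablation modes are definitional: `unweighted` runs the weighted path
with all-ones maps (bit-identical results), `2d_only`/`3d_only` zero
the other map.

Defaults: max 100 iterations, gradient tolerance 1e-9, relative
objective tolerance 1e-12, identity initialization for a single solve
and previous-twist (constant-velocity) initialization along sequences;
a non-converged frame falls back to its initialization with a warning
rather than aborting the sequence.

## Declarative training layer

At a stationary `p*`, the implicit function theorem gives
`dp*/dω = −H⁻¹B` with `H = ∂²f/∂p²` (exact, 6×6) and `B = ∂²f/∂p∂ω`
(assembled from per-pixel first-order tangents; memory linear in |Ω|).
The training loss is `‖p* − p_gt‖₁` with subgradient fixed to 0 at zero
components. Solutions whose gradient ∞-norm exceeds 1e-6 are rejected
(the formula is meaningless away from a minimum); near-singular
Hessians are Levenberg-damped with λ ∈ {0, 1e-9, 1e-6, 1e-3}, first
positive-definite value wins, and the damping is recorded. Non-converged
batch elements are skipped with a log entry; an all-skipped batch raises.

The two weight networks are independent 3-resolution-level
encoder–decoders (two 3×3 conv + ReLU per level, base width 16 doubling
per level, average-pool down, nearest-neighbour up, skip connections,
1×1 conv + sigmoid head). Inputs are the residual ingredients,
channel-stacked and normalized to comparable scale: images in [0,1],
depth already in (0,1], flows divided by (X, Y) — 8 channels for ω_2D,
14 for ω_3D (which also sees the previous frame). The networks and
their backpropagation are implemented directly in numpy (strided-window
convolutions); Adam is the optimizer.

Training splits pairs 80/20 into train/validation, uses batch size 8
and early stopping on the validation loss (best parameters kept). The
desk-scale preset trains at 32×40 for ≤15 epochs with Adam 1e-3 — the
standard learning-rate regime for a ~10⁵-parameter network trained from
scratch on a few hundred samples; `TrainConfig.fullscale()` preserves
the full-data regime (half-resolution inputs, Adam 1e-5, 200 epochs)
for users with real data and the hardware to match. Training pairs span
frame intervals 1–5 and balance "moving" and "static" frames (labelled
from the ground-truth kinematics) to within one.

## Synthetic scenes

The generator emulates the inputs of endoscopic VO with exact,
mutually consistent ground truth. Units are millimetres; the defaults
model an endoscopic working volume: surfaces around 60 mm (base plane
at 0.6 × the 100 mm maximum expected depth) with 6 Gaussian bumps of up
to 8 mm height and 10–22 mm width, stereo baseline 4.5 mm, focal length
0.9 × image width, breathing of 1 mm amplitude and 25-frame period,
tool pokes of 5 mm within a 12 mm radius pulsing over 20 frames, camera
twists ≤ 0.01 (∞-norm, normalized units) per frame, 150-frame default
clips. Four scenarios: `rigid` (camera motion only), `breathing`
(tissue motion, static camera), `scanning` (both), `deforming` (static
camera, local poke).

Geometry is a height field over world XY; tissue displacement is a 3-D
field over material coordinates. The tool poke pushes along an oblique
unit direction (0.55, 0.35, −0.76): instruments rarely push straight
down the optical axis, and the lateral component is what makes a poke
visible in optical flow rather than only in depth. Depth is rendered by
ray casting (joint fixed-point iteration on ray depth and material
labels, tolerance 1e-12); temporal flow for any frame interval, stereo
disparity and poses all derive from the same forward model, so with
zero deformation the flow-pose-depth consistency residual is below
0.05 px by construction — the generator is its own oracle. Per-frame
deformation masks flag pixels whose displacement *changed* by more than
5% of that pair's peak motion — the support of the signal the weight
networks must detect. Optional corruptions (Gaussian flow/depth noise,
a low-texture corruption patch, specular highlights, an instrument
wedge) emulate estimator failure modes; they default off except
specularities.

What the generator does **not** model: occlusions (surfaces are
single-valued and viewed near-frontally; camera motion is bounded
accordingly), photometric effects beyond procedural texture and
stamped highlights, smoke, bleeding, fluid, tissue tearing, rolling
shutter, calibration error. Passing tests therefore demonstrate the
correctness of the geometry, the optimization and the learning
machinery under exact and mildly-noised inputs — not robustness to the
full pathology of real surgical video.

**Accuracy floor of the 3-D residual.** Bilinear warping of a point
cloud is exact only when the cloud is affine in pixel coordinates
(planar surface, translation-only motion). On curved surfaces at 64×80
the interpolation floor is ~1e-7 (normalized) per pixel and biases the
pose argmin by ~1.5e-5 in twist norm; this is a property of the warp,
not of the solver. Verification studies therefore separate concerns:
residual exactness and machine-precision pose recovery are checked on
planar scenes (where the argmin provably coincides with ground truth),
and curved-surface recovery is characterized separately at the warp
floor (~5e-5).

## Metrics

ATE-RMSE aligns estimated positions onto ground truth with the
closed-form SVD rigid alignment (no scale — stereo is metric) and
reports the position RMSE. RPE composes per-step error transforms over
a configurable span (default 1 frame) and reports mean ± std of the
translation norm and of the rotation angle, the latter extracted with
the atan2 form (the arccos-of-trace form loses half the digits near
zero rotation). The test suite checks both against an independently
coded reference (Horn's quaternion alignment; explicit per-step matrix
algebra) to 1e-9. Timestamp association is exact for synthetic data,
nearest-neighbour within 0.02 s for external TUM files.

## Problem sizes used in the verification studies

Pose-recovery and weighting studies run at 64×80 over 8- and 6-frame
clips (10 and 20 seeds); the implicit-gradient oracle uses 8×8–16×16
frames with flow noise σ = 0.3 px; training runs at 32×40 with 200
pairs from five 30-frame deforming clips, ≤8 epochs, patience 4. These
sizes keep every study CPU-friendly while leaving each measured margin
orders of magnitude clear of its bound.

## Files and formats

TUM trajectories (`timestamp tx ty tz qx qy qz qw`), 16-bit PNG depth
with a declared counts-per-unit scale (sequence directories default to
using the full 16-bit range over the configured working volume),
Middlebury `.flo` flow, 8-bit PNG masks (0 = masked) and images, flat
YAML configs, and `.npz` checkpoints holding both networks' parameters
plus architecture metadata.
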