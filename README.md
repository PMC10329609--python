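# endovo

Stereo visual odometry for endoscopic surgery with learned per-pixel
residual weighting.

Tracking the camera of a stereo endoscope is hard for classical
rigid-scene SLAM: tissue deforms under instruments, organs move with
breathing, and specularities and textureless regions corrupt optical
flow and depth. `endovo` estimates frame-to-frame camera motion purely
from geometry — dense temporal optical flow and stereo depth are inputs,
not outputs — and learns *where in the image to look*: two small
encoder–decoder networks produce per-pixel weights that attenuate
ambiguous regions (deforming tissue, bad flow) inside the pose
optimization itself.

## The model

For each pixel **x** of frame *t*, with normalized depth map `D_t`,
temporal flow `F_t` (frame *t* → *t−1*) and relative pose
`p_t ∈ se(3)` (twist; translation in normalized depth units):

* **2-D residual** — re-project the frame-*t* point moved by the
  candidate pose and compare with the flow correspondence, scaled per
  axis by the image dimensions X, Y:

  `r_2D(p, x) = ‖ ( π_2D( exp(p) · π_3D(D_t, x) ) − (x + F_t(x)) ) / (X, Y) ‖₂`

* **3-D residual** — point-to-point distance to the previous frame's
  point cloud, bilinearly warped to the flow target:

  `r_3D(p, x) = ‖ exp(p) · π_3D(D_t, x) − π_3D(D_{t−1}, x + F_t(x)) ‖₂`

* **weighted objective** — with learned maps `ω_2D, ω_3D ∈ [0, 1]`:

  `p* = argmin_p Σ_x ( ω_2D(x) r_2D(p, x) + ω_3D(x) r_3D(p, x) )²`

solved by L-BFGS with exact forward-mode gradients, plus a damped-Newton
polish to true stationarity. Chaining the per-pair `exp(p*)` gives the
trajectory.

The weight networks (3-level UNets with a sigmoid head) see exactly the
residual ingredients (image, depth, temporal and parallax flow — 8
channels for ω_2D, 14 for ω_3D) and are trained **through the argmin**:
the pose solve is a declarative layer differentiated implicitly,
`dp*/dω = −H⁻¹ B` with `H = ∂²f/∂p²` and `B = ∂²f/∂p∂ω`, so the l1 loss
`‖p* − p_gt‖₁` backpropagates into both networks.

Because real surgical video with ground-truth kinematics is not
shippable, the package includes a synthetic surgical-scene generator
(smooth organ-like surfaces, breathing, oblique tool pokes, specular
highlights, instrument masks) whose depth / flow / disparity / pose
ground truth is mutually consistent by construction — it is the test
substrate and the training data source. ATE-RMSE and RPE trajectory
metrics complete the pipeline.

## Worked example

```python
import numpy as np
from endovo import (SceneConfig, render_sequence, SolverConfig,
                    PoseModel, run_odometry, ate_rmse, rpe)

cfg = SceneConfig(scenario="scanning", n_frames=10, seed=42)   # camera motion + breathing
seq = render_sequence(cfg)
obs = seq.frame_observations()

fit = PoseModel(obs[1], obs[0], config=SolverConfig(mode="unweighted")).fit()
print(fit.summary())
```

```
Relative pose (NLLS over se(3))
==============================================
pixels in Omega      4665
mode                 unweighted
objective            2.560463e-04
gradient inf-norm    9.011e-10
iterations           30
converged            True
----------------------------------------------
 param       estimate      std err
    tx    -0.00346032    6.814e-06
    ty    -0.00462199    8.963e-06
    tz    -0.00227638    2.087e-06
    wx     0.00940601    1.417e-05
    wy    -0.00280188    1.036e-05
    wz     0.00577626    4.809e-06
==============================================
```

The estimated twist (translation in units of the 100 mm maximum depth,
rotation in radians) sits close to the generator's ground truth
`(-3.50e-3, -4.57e-3, -6.5e-5, 9.48e-3, -2.73e-3, 5.78e-3)`; the
residual misfit (objective 2.6e-4 instead of ~0) is the breathing
deformation this scenario contains — exactly the signal the weight maps
learn to suppress. Chaining all nine pairs and scoring:

```python
traj, results = run_odometry(obs, config=SolverConfig(mode="unweighted",
                                                      init_policy="previous"))
est_mm = traj.scaled_translation(cfg.max_expected_depth)
print(ate_rmse(seq.trajectory, est_mm))          # 0.1494  (mm)
print(rpe(seq.trajectory, est_mm))               # 0.1221 +/- 0.0689 mm, 0.0108 +/- 0.0057 deg
```

The same pipeline is scriptable from the shell:

```bash
endovo simulate --config scene.yaml --out seq/ --seed 3
endovo solve --frames seq/left --flows seq/flow --depths seq/depth \
             --masks seq/mask --parallax seq/parallax \
             --config seq/scene.yaml --mode unweighted --out est.txt
endovo evaluate --gt seq/groundtruth.txt --est est.txt
endovo train --data train_scenes.yaml --out weights.npz --epochs 15 --seed 0
```

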