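# synglove

Synergy-based under-sensed hand pose reconstruction: estimate a full
19-degree-of-freedom (DOF) hand posture from only a handful of measured
joint angles, choose *which* joints a glove should sense, calibrate textile
bend sensors, and recognize functional grasps without supervision.

## The problem

Wearable sensing gloves face a hard trade-off: accurate hand kinematics
needs many sensors, but ergonomics, wiring and cost cap the number that can
be integrated. Human grasping postures, however, are highly structured —
joint angles covary along a few *postural synergies* — so a small number of
well-placed sensors plus statistical prior knowledge can recover the whole
posture. This package implements that program for a 19-DOF kinematic hand
model (thumb abduction/rotation/metacarpal flexion; per-finger abduction and
MCP/PIP/DIP flexion, with each DIP slaved to its PIP by θ_D = ⅔·θ_P), aimed
at motor-control studies, rehabilitation monitoring and low-cost interfaces.

## The method

Write a hand pose as x ∈ ℝⁿ (n = 19, degrees) and the glove readings as

    y = H x + ν,     H ∈ ℝ^{m×n},  m < n,

where each row of H is a canonical basis vector (one sensor = one joint) and
ν is zero-mean Gaussian noise with covariance R. An ensemble of grasp
postures X summarizes the synergy information as a Gaussian prior with mean
μ_o and covariance P_o = (X − x̄)(X − x̄)ᵀ/(N−1). The minimum-variance
estimate of the pose and its residual uncertainty are

    x̂  = μ_o − P_o Hᵀ (H P_o Hᵀ + R)⁻¹ (H μ_o − y)
    P_p = P_o − P_o Hᵀ (H P_o Hᵀ + R)⁻¹ H P_o,

equivalently x̂ = (P_o⁻¹ + Hᵀ R⁻¹ H)⁻¹ (Hᵀ R⁻¹ y + P_o⁻¹ μ_o) when P_o and
R are invertible (both forms are implemented; the first is the default since
the coupled prior is rank-deficient and the glove operates at R = 0, where
measured joints are interpolated exactly). Sensor placement is chosen by
minimizing the squared Frobenius norm ‖P_p‖²_F over all joint subsets of
size m — exhaustively (C(19,5) = 11,628 subsets) or greedily.

Around this core the package provides: an affine goniometer model
ΔR = s_θ·θ + ΔR₀ with exact two-point calibration θ = α₁ΔR + α₂ (defaults
0°/90°); a synthetic generator of synergy-structured grasp ensembles and
multi-subject labeled panels; and the grasp-recognition protocol — K-means
with squared Euclidean distance, cluster centroids seeded from one held-out
subject's mean poses (leave-one-subject-out), scored by per-grasp relative
and overall absolute accuracy from confusion matrices.

## Worked example

```python
import numpy as np
from synglove import (default_generator, sample_prior_set, estimate_prior,
                      select_exhaustive, build_selection_matrix,
                      extract_measurements, MeasurementSet, mve_estimate)

gen = default_generator(seed=0)
X = sample_prior_set(gen, 2000, seed=1)          # a-priori grasp ensemble
prior = estimate_prior(X)

design = select_exhaustive(prior, m=5)           # which 5 joints to sense?
print("optimal joints:", ",".join(design.joints))

pose = sample_prior_set(gen, 2, seed=99)[:, 0]   # a new grasp to reconstruct
sel = build_selection_matrix(design.joints)
y = extract_measurements(pose, sel)              # the 5 glove readings
est = mve_estimate(prior, MeasurementSet(sel=sel, y=y))

unmeasured = np.setdiff1d(np.arange(19), sel.indices)
rmse = np.sqrt(np.mean((est.x_hat[unmeasured] - pose[unmeasured])**2))
print(f"RMSE over the 14 unmeasured joints: {rmse:.2f} deg")
```

prints

```
optimal joints: TR,MP,RA,LA,LP
RMSE over the 14 unmeasured joints: 1.54 deg
```

Five sensors plus the synergy prior reconstruct the fourteen unseen joints
to 1.5° RMS here, versus 3.0° from the prior mean alone; the five measured
joints are reproduced to machine precision because R = 0. (The optimal
subset depends on the prior: for the original glove study's motion-capture
prior it was TA, MM, RP, LA, LM.)

The same flow is scriptable from the shell:

```
synglove pipeline --seed 1 --out-dir out/
```

runs simulate → prior → design → reconstruct (through simulated goniometer
windows) → recognize, and writes pose CSVs, the prior JSON, the design
report, five per-subject confusion matrices and an accuracy summary. See
`synglove --help` for the individual subcommands.

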