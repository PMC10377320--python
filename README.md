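# limbmanip

Human upper-limb **manipulability** and **surface-EMG effort** analysis.

For researchers in movement biomechanics and rehabilitation who want to
quantify, from commodity sensors, (a) how freely the arm's endpoint can
move at each instant of an exercise and (b) how hard each muscle is
working while it does.  The package models the right arm as a 6-DOF
serial kinematic chain driven by depth-camera skeleton data, derives
scalar manipulability indices from its Jacobian, processes 4-channel
sEMG (flexor/extensor carpi ulnaris, biceps brachii, deltoideus medius)
into MVC-normalised envelopes and per-phase effort metrics, and compares
muscles statistically.  A seeded synthetic-data generator reproduces the
structure of such recordings (19 participants x 2 scripted exercises x
10 trials) so the whole analysis can be exercised and tested without any
lab data.

## Model

**Kinematics.** The arm is a three-segment chain (upper arm L1, forearm
L2, hand L3) with six revolute joints: shoulder abduction/adduction q1,
shoulder flexion/extension q2, internal rotation q3, elbow
flexion/extension q4, pronation/supination q5, wrist flexion/extension
q6.  Standard Denavit–Hartenberg rows (Rz(θ)·Tz(d)·Tx(a)·Rx(α)) define
the chain; the geometric Jacobian J ∈ ℝ⁶ˣ⁶ stacks linear over angular
velocity rows, column i being [z_{i−1} × (p_e − p_{i−1}); z_{i−1}].

**Indices.** From the singular values σ₁ ≥ … ≥ σ₆ of J:

- KMI (Yoshikawa manipulability) `w = sqrt(det(J Jᵀ)) = Πσᵢ = |det J|` — 0 at a singularity;
- dexterity index `Id = ‖J‖₂·‖J⁻¹‖₂ = σ₁/σ₆` — the condition number;
- LCI `= 1/Id = σ₆/σ₁ ∈ [0, 1]` — 1 isotropic, 0 singular.

Joint angles come from skeleton frames: q1/q2 from the upper-arm
direction in a trunk frame, q4 and q6 from inter-segment angles (q3 and
q5 are unobservable from joint positions and flagged).

**EMG.** Each channel (μV, 1500 Hz) passes a fixed pipeline: 8th-order
Butterworth band-pass 20–300 Hz (zero-phase) → full-wave rectification →
3500-bin running-median envelope → division by the muscle's maximum
voluntary contraction (MVC).  Per exercise phase, on the band-passed
signal of length L:

- `RMS = sqrt(1/L Σ xᵢ²)`, `MAV = 1/L Σ |xᵢ|`,
- `WL = Σ |x_{i+1} − xᵢ|`,
- `SSC = Σ 1[(xᵢ − x_{i−1})(xᵢ − x_{i+1}) ≥ θ]` with θ = 100 μV.

**Statistics.** One value per participant (trial mean); two-sided
Wilcoxon rank-sum tests over all C(4,2) = 6 muscle pairs per
(metric, phase) cell, significant below the Bonferroni threshold
α/6 = 0.05/6 ≈ 0.008.

## Worked example

`examples/` holds one short script per capability.
`python examples/02_exercise_indices.py` generates a noise-free trial of
the frontal-plane exercise, recovers the joint angles from the rendered
skeleton and prints the index profile:

```
frames: 480 at 30 Hz; angle recovery error: 3.53e-15 rad
peak KMI 2.249e-02 at t = 6.80 s
  abduction          [ 2.0- 4.0 s]  mean KMI 2.013e-04  mean LCI 0.0070
  elbow_flexion      [ 4.0- 6.0 s]  mean KMI 1.179e-02  mean LCI 0.0551
  elbow_extension    [ 6.0- 8.0 s]  mean KMI 1.219e-02  mean LCI 0.0572
  wrist_flexion      [ 8.0-10.0 s]  mean KMI 5.025e-04  mean LCI 0.0088
  wrist_extension    [10.0-12.0 s]  mean KMI 5.025e-04  mean LCI 0.0088
  return             [12.0-14.0 s]  mean KMI 2.865e-04  mean LCI 0.0079
```

The indices peak while the elbow travels through mid-flexion and
collapse during the extended-arm wrist phases — full elbow extension is
the chain's singular configuration, where the hand cannot move along
the arm axis.  `examples/03_emg_features.py` shows the EMG side: the
muscle scripted to drive each phase carries the top per-phase RMS
(e.g. DM 231.7 μV during abduction, ECU 318.2 μV during wrist
extension).

The same pipeline runs from the shell:

```sh
limbmanip generate --seed 1 --out cohort/   # synthetic cohort file tree
limbmanip validate cohort/                  # schema/rate checks
limbmanip run --input cohort/ --out results/
```

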