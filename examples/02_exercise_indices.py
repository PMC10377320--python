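"""Manipulability index time series over a scripted exercise.

Generates one noise-free trial of the frontal-plane exercise (abduction
-> elbow flexion/extension -> wrist flexion/extension -> return),
recovers the joint angles from the rendered skeleton stream, computes
KMI/LCI per frame and reports where in the trial the indices peak.
"""

import numpy as np

from limbmanip import (
    EXERCISE_1,
    GeneratorConfig,
    default_dh_table,
    extract_sequence,
    generate_skeleton,
    indices_over_trajectory,
)

cfg = GeneratorConfig(seed=0, joint_noise_m=0.0, duration_jitter=0.0)
skeleton, truth = generate_skeleton(EXERCISE_1, cfg)
poses = extract_sequence(skeleton, smooth_window=1)
series = indices_over_trajectory(default_dh_table(cfg.lengths_mean), poses)

recovery = np.max(np.abs(poses.angles() - truth.angles())[:, [0, 1, 3, 5]])
print(f"frames: {len(series)} at 30 Hz; angle recovery error: {recovery:.2e} rad")

t = series.timestamps
peak = t[np.argmax(series.kmi)]
phase_starts = np.cumsum([EXERCISE_1.rest_before] + [p.duration for p in EXERCISE_1.phases])
print(f"peak KMI {series.kmi.max():.3e} at t = {peak:.2f} s")
for name, t0, t1 in zip(
    [p.name for p in EXERCISE_1.phases], phase_starts[:-1], phase_starts[1:]
):
    mask = (t >= t0) & (t < t1)
    print(
        f"  {name:18s} [{t0:4.1f}-{t1:4.1f} s]  "
        f"mean KMI {series.kmi[mask].mean():9.3e}  mean LCI {series.lci[mask].mean():.4f}"
    )

print(
    "\nThe indices rise while the elbow travels through mid-flexion"
    "\n(phases 2-3) and collapse during the extended-arm wrist phases:"
    "\nfull extension is the model's singular configuration."
)
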