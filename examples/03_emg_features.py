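"""Surface-EMG preprocessing and per-phase effort metrics.

Generates a two-trial sEMG recording for the frontal-plane exercise,
runs the fixed pipeline (band-pass -> rectify -> median envelope ->
MVC-normalise), segments trials with the emitted markers and prints the
per-phase RMS of each muscle: the muscle scripted to drive each phase
should carry the largest RMS there.
"""

import numpy as np

from limbmanip import (
    EXERCISE_1,
    MUSCLES,
    GeneratorConfig,
    bandpass_filter,
    envelope,
    generate_emg,
    mvc_normalize,
    rectify,
    rms,
    segment_trials,
)

cfg = GeneratorConfig(seed=0)
rec, markers, truth = generate_emg(EXERCISE_1, cfg, n_trials=2, rng_key=(0, 0))
print(f"recording: {rec.duration:.1f} s x {len(rec.channels)} channels @ {rec.rate:.0f} Hz")

seg = segment_trials(rec, markers, EXERCISE_1.phase_fractions)
filtered = {m: bandpass_filter(rec.channels[m], rec.rate) for m in MUSCLES}

w = seg.trials[0]
print(f"\ntrial 0 per-phase RMS (uV), band-passed signal:")
header = "  ".join(f"{m.upper():>6s}" for m in MUSCLES)
print(f"{'phase':18s} {header}   top (designed)")
for pi, (s, e) in enumerate(seg.phase_windows(w)):
    values = {m: rms(filtered[m][s:e]) for m in MUSCLES}
    top = max(values, key=values.get)
    designed = EXERCISE_1.designed_top_muscle(pi, cfg.mvc_uv)
    row = "  ".join(f"{values[m]:6.1f}" for m in MUSCLES)
    print(f"{EXERCISE_1.phases[pi].name:18s} {row}   {top} ({designed})")

env = mvc_normalize(
    envelope(rectify(filtered["dm"]), 3500), cfg.mvc_uv["dm"]
)
a0, a1 = w.activity_start, w.activity_end
print(
    f"\nDM normalized envelope: activity mean {env[a0:a1].mean():.3f}, "
    f"rest mean {env[: a0].mean():.3f} (fraction of MVC)"
)
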