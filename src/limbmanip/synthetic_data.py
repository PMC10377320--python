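"""Synthetic skeleton + sEMG cohort generator.

Emulates the structure of the study's recordings so the whole analysis
is testable without the archived deposit: per trial, a scripted arm
trajectory (minimum-jerk between phase targets) rendered to 30 Hz
skeleton frames through the forward kinematics, and a 4-channel 1500 Hz
sEMG recording built as a band-limited Gaussian carrier, amplitude-
modulated by trapezoidal phase-locked activation envelopes (level x
MVC) on top of ~5 uV RMS baseline noise.  Trigger and activity markers
are emitted at known sample indices, and every ground truth (joint
angles, activation envelopes, trial windows) is returned or written to
a manifest.

What it deliberately does *not* model: motor-unit firing statistics,
electrode crosstalk, skeleton occlusions, and any EMG-kinematics
coupling beyond the scripted phase structure.

Exercise scripts
----------------
``EXERCISE_1`` (frontal plane): abduction to 90 deg, elbow flexion to
the forehead, elbow extension, wrist flexion + return, wrist extension
+ return, return to rest.  ``EXERCISE_2`` (transverse plane): abduction,
elbow flexion to the chest held through wrist flexion and extension,
then elbow extension + return.  Phase durations default to 2 s with 2 s
rests; the model's neutral (straight-hand) wrist is q6 = pi/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .arm_kinematics import (
    ArmPose,
    DHTable,
    PoseTimeSeries,
    default_dh_table,
    forward_kinematics,
)
from .emg_pipeline import (
    MUSCLES,
    EMGRecording,
    Marker,
    MVCTable,
    bandpass_filter,
    write_emg_csv,
    write_markers_csv,
    write_mvc_csv,
)
from .pose_extraction import SkeletonFrame, SkeletonSequence, write_skeleton_csv

__all__ = [
    "ExercisePhase",
    "ExerciseScript",
    "GeneratorConfig",
    "EXERCISE_1",
    "EXERCISE_2",
    "DEFAULT_MVC_UV",
    "REST_Q",
    "SCRIPTS",
    "script_angles",
    "activation_envelope",
    "generate_skeleton",
    "generate_emg",
    "generate_mvc_recording",
    "participant_profile",
    "generate_cohort",
]

HALF_PI = float(np.pi / 2)

#: neutral posture: arm hanging with a slight elevation and elbow bend
#: (a perfectly straight elbow is the model's singular pose and also not
#: how people actually stand), straight hand.
REST_Q = (0.0, 0.10, 0.0, 0.12, 0.0, HALF_PI)

#: per-muscle maximum voluntary contraction defaults, microvolts.
DEFAULT_MVC_UV = {"fcu": 420.0, "ecu": 480.0, "bb": 520.0, "dm": 380.0}


@dataclass(frozen=True)
class ExercisePhase:
    """One scripted movement phase.

    ``targets`` maps joint index (1-based) to the angle reached at the
    end of the phase; ``via`` optionally to a mid-phase waypoint (used
    for flex-and-return wrist movements).  ``activation`` maps muscle to
    its plateau level as a fraction of MVC.
    """

    name: str
    duration: float
    targets: dict[int, float] = field(default_factory=dict)
    via: dict[int, float] = field(default_factory=dict)
    activation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if any(not (0.0 <= v <= 1.0) for v in self.activation.values()):
            raise ValueError("activation levels must lie in [0, 1]")


@dataclass(frozen=True)
class ExerciseScript:
    name: str
    phases: tuple[ExercisePhase, ...]
    rest_before: float = 2.0
    rest_after: float = 2.0
    start_q: tuple[float, ...] = REST_Q

    @property
    def activity_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))

    @property
    def duration(self) -> float:
        return self.rest_before + self.activity_duration + self.rest_after

    @property
    def phase_fractions(self) -> tuple[float, ...]:
        """Interior phase boundaries as fractions of the activity window."""
        cum = np.cumsum([p.duration for p in self.phases])[:-1]
        return tuple(float(c / self.activity_duration) for c in cum)

    def designed_top_muscle(self, phase_index: int, mvc: dict[str, float]) -> str:
        """The muscle whose designed level x MVC is largest in a phase."""
        act = self.phases[phase_index].activation
        return max(MUSCLES, key=lambda m: act.get(m, 0.0) * mvc[m])


def scale_script(script: "ExerciseScript", scale: float) -> "ExerciseScript":
    """Uniformly stretch every phase and rest duration by ``scale``."""
    return ExerciseScript(
        name=script.name,
        phases=tuple(replace(ph, duration=ph.duration * scale) for ph in script.phases),
        rest_before=script.rest_before * scale,
        rest_after=script.rest_after * scale,
        start_q=script.start_q,
    )


def _phase(name, duration, targets, activation, via=None):
    return ExercisePhase(name, duration, targets, via or {}, activation)


EXERCISE_1 = ExerciseScript(
    name="exercise_1",
    phases=(
        _phase("abduction", 2.0, {2: HALF_PI},
               {"dm": 0.45, "bb": 0.10, "fcu": 0.05, "ecu": 0.08}),
        _phase("elbow_flexion", 2.0, {4: 2.2},
               {"dm": 0.43, "bb": 0.30, "fcu": 0.05, "ecu": 0.08}),
        _phase("elbow_extension", 2.0, {4: 0.15},
               {"dm": 0.41, "bb": 0.18, "fcu": 0.05, "ecu": 0.08}),
        _phase("wrist_flexion", 2.0, {6: HALF_PI},
               {"fcu": 0.40, "dm": 0.35, "ecu": 0.10, "bb": 0.08},
               via={6: HALF_PI + 0.9}),
        _phase("wrist_extension", 2.0, {6: HALF_PI},
               {"ecu": 0.52, "dm": 0.35, "fcu": 0.08, "bb": 0.08},
               via={6: HALF_PI - 0.9}),
        _phase("return", 2.0, {2: 0.10, 4: 0.12},
               {"dm": 0.25, "bb": 0.06, "fcu": 0.05, "ecu": 0.06}),
    ),
)

EXERCISE_2 = ExerciseScript(
    name="exercise_2",
    phases=(
        _phase("abduction", 2.0, {2: HALF_PI},
               {"dm": 0.45, "bb": 0.10, "fcu": 0.05, "ecu": 0.08}),
        _phase("elbow_flexion", 2.0, {4: 1.7},
               {"bb": 0.35, "dm": 0.35, "fcu": 0.05, "ecu": 0.08}),
        _phase("wrist_flexion", 2.0, {6: HALF_PI},
               {"fcu": 0.40, "dm": 0.30, "bb": 0.15, "ecu": 0.10},
               via={6: HALF_PI + 0.9}),
        _phase("wrist_extension", 2.0, {6: HALF_PI},
               {"ecu": 0.45, "dm": 0.30, "bb": 0.15, "fcu": 0.08},
               via={6: HALF_PI - 0.9}),
        _phase("elbow_extension_return", 2.0, {2: 0.10, 4: 0.12},
               {"dm": 0.30, "bb": 0.10, "fcu": 0.05, "ecu": 0.08}),
    ),
)

SCRIPTS = {"exercise_1": EXERCISE_1, "exercise_2": EXERCISE_2}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator settings (defaults mirror the study design)."""

    seed: int = 0
    n_participants: int = 19
    n_trials: int = 10
    skeleton_rate: float = 30.0
    emg_rate: float = 1500.0
    baseline_noise_uv: float = 5.0
    mvc_uv: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MVC_UV))
    joint_noise_m: float = 0.005
    lengths_mean: tuple[float, float, float] = (0.30, 0.25, 0.18)
    lengths_sd: tuple[float, float, float] = (0.02, 0.015, 0.01)
    mvc_subject_sd: float = 0.15  # lognormal-ish per-participant MVC scale
    activation_jitter: float = 0.05  # per-trial multiplicative level jitter
    duration_jitter: float = 0.08  # per-trial multiplicative duration jitter
    ramp_s: float = 0.3  # activation trapezoid rise/fall time

    def __post_init__(self) -> None:
        if self.skeleton_rate <= 0 or self.emg_rate <= 0:
            raise ValueError("rates must be positive")
        if self.baseline_noise_uv < 0 or self.joint_noise_m < 0:
            raise ValueError("noise levels must be non-negative")


def _rng(cfg: GeneratorConfig, *key: int) -> np.random.Generator:
    # one stream per (seed, participant, exercise, trial, channel):
    # regenerating any sub-tree reproduces the same data
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def _min_jerk(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def script_angles(script: ExerciseScript, t: np.ndarray) -> np.ndarray:
    """Joint angles (len(t), 6) of the scripted trajectory at times ``t``
    measured from trial start (rest included)."""
    q = np.tile(np.asarray(script.start_q, dtype=float), (len(t), 1))
    # build per-joint piecewise segments (start_time, duration, q0, q1)
    segs: list[tuple[float, float, int, float, float]] = []
    current = dict(enumerate(script.start_q, start=1))
    t0 = script.rest_before
    for ph in script.phases:
        joints = set(ph.targets) | set(ph.via)
        for j in joints:
            q0 = current[j]
            if j in ph.via:
                mid = ph.via[j]
                end = ph.targets.get(j, q0)
                segs.append((t0, ph.duration / 2, j, q0, mid))
                segs.append((t0 + ph.duration / 2, ph.duration / 2, j, mid, end))
                current[j] = end
            else:
                end = ph.targets[j]
                segs.append((t0, ph.duration, j, q0, end))
                current[j] = end
        t0 += ph.duration
    for start, dur, j, q0, q1 in segs:
        s = _min_jerk((t - start) / dur)
        mask = t >= start
        q[mask, j - 1] = q0 + (q1 - q0) * s[mask]
        q[t >= start + dur, j - 1] = q1
    return q


def _camera_isometry(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # a mild random camera placement: rotation < ~20 deg plus offset
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-0.35, 0.35)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    trans = rng.normal(scale=0.5, size=3) + np.array([0.0, 0.0, 2.0])
    return R, trans


def generate_skeleton(
    script: ExerciseScript,
    cfg: GeneratorConfig,
    table: DHTable | None = None,
    rng: np.random.Generator | None = None,
    camera: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[SkeletonSequence, PoseTimeSeries]:
    """Render one trial's scripted trajectory to skeleton frames.

    Returns the (noisy, camera-frame) skeleton sequence and the exact
    ground-truth pose series driving it.  With ``joint_noise_m = 0`` and
    the identity camera the round trip through pose extraction is exact
    for q1, q2, q4, q6.
    """
    if table is None:
        table = default_dh_table(cfg.lengths_mean)
    if rng is None:
        rng = _rng(cfg, 0)
    t = np.arange(0.0, script.duration, 1.0 / cfg.skeleton_rate)
    q = script_angles(script, t)
    if camera is None:
        R, trans = _camera_isometry(rng)
    else:
        R, trans = camera

    # trunk landmarks in the model base frame (shoulder at the origin,
    # z down the trunk, x medial)
    spine_shoulder = np.array([0.18, 0.0, -0.02])
    hip_center = spine_shoulder + np.array([0.0, 0.0, 0.55])
    shoulder = np.zeros(3)

    frames = []
    poses = []
    for i, ti in enumerate(t):
        pose = ArmPose.from_array(q[i])
        poses.append(pose)
        _, chain = forward_kinematics(table, pose)
        pts = {
            "spine_shoulder": spine_shoulder,
            "hip_center": hip_center,
            "shoulder_r": shoulder,
            "elbow_r": chain[3][:3, 3],
            "wrist_r": chain[5][:3, 3],
            "hand_tip_r": chain[6][:3, 3],
        }
        noisy = {}
        for name, p in pts.items():
            p_cam = R @ p + trans
            if cfg.joint_noise_m > 0:
                p_cam = p_cam + rng.normal(scale=cfg.joint_noise_m, size=3)
            noisy[name] = p_cam
        frames.append(SkeletonFrame(timestamp=float(ti), **noisy))
    return SkeletonSequence(tuple(frames)), PoseTimeSeries(t, tuple(poses))


def activation_envelope(
    script: ExerciseScript, t: np.ndarray, muscle: str, ramp_s: float = 0.3
) -> np.ndarray:
    """Trapezoidal activation (fraction of MVC) at times ``t`` from trial
    start: plateaus at each phase's designed level with linear ramps of
    ``ramp_s`` seconds centred on the phase boundaries."""
    bounds = [script.rest_before]
    for ph in script.phases:
        bounds.append(bounds[-1] + ph.duration)
    levels = [0.0] + [ph.activation.get(muscle, 0.0) for ph in script.phases] + [0.0]
    # piecewise-linear through (boundary +- ramp/2) nodes
    xs = [0.0]
    ys = [0.0]
    for k, b in enumerate(bounds):
        xs.extend([b - ramp_s / 2, b + ramp_s / 2])
        ys.extend([levels[k], levels[k + 1]])
    xs.append(script.duration)
    ys.append(0.0)
    return np.interp(t, xs, ys)


def generate_emg(
    script: ExerciseScript,
    cfg: GeneratorConfig,
    n_trials: int | None = None,
    mvc: dict[str, float] | None = None,
    rng_key: tuple[int, ...] = (),
) -> tuple[EMGRecording, list[Marker], dict]:
    """Generate a multi-trial sEMG recording with markers.

    Each channel is ``carrier(t) * level(t) * MVC + baseline`` where the
    carrier is unit-RMS Gaussian noise band-limited to 20-300 Hz and the
    baseline is white noise at ``cfg.baseline_noise_uv`` RMS.  Trials are
    laid back-to-back (each already contains its rest padding); trigger
    markers bracket whole trials and activity markers the movement.

    Returns the recording, the marker list and a ground-truth dict with
    per-trial windows, per-trial duration scale factors and the designed
    activation envelopes.
    """
    if n_trials is None:
        n_trials = cfg.n_trials
    if mvc is None:
        mvc = dict(cfg.mvc_uv)
    fs = cfg.emg_rate

    trial_scales = []
    trial_windows = []
    envelopes = {m: [] for m in MUSCLES}
    chunks: dict[str, list[np.ndarray]] = {m: [] for m in MUSCLES}
    cursor = 0
    markers: list[Marker] = []
    truth_trials = []
    for trial in range(n_trials):
        rng_t = _rng(cfg, *rng_key, trial)
        scale = 1.0
        if cfg.duration_jitter > 0:
            scale = float(
                np.clip(rng_t.normal(1.0, cfg.duration_jitter), 0.7, 1.3)
            )
        scaled = scale_script(script, scale)
        n = int(round(scaled.duration * fs))
        t = np.arange(n) / fs
        jitter = {}
        for m in MUSCLES:
            jitter[m] = float(np.clip(rng_t.normal(1.0, cfg.activation_jitter), 0.5, 1.5))
        for ci, m in enumerate(MUSCLES):
            rng_c = _rng(cfg, *rng_key, trial, ci)
            carrier = rng_c.normal(size=n)
            carrier = bandpass_filter(carrier, fs)
            # unit *median absolute* amplitude: the running-median envelope
            # of the rectified signal then reads off level * MVC directly
            # (the RMS is ~1.49x that for a Gaussian carrier)
            carrier /= np.median(np.abs(carrier))
            level = activation_envelope(scaled, t, m, cfg.ramp_s) * jitter[m]
            x = carrier * level * mvc[m]
            if cfg.baseline_noise_uv > 0:
                x = x + rng_c.normal(scale=cfg.baseline_noise_uv, size=n)
            chunks[m].append(np.clip(x, -4999.0, 4999.0))
            envelopes[m].append(level * mvc[m])
        a0 = cursor + int(round(scaled.rest_before * fs))
        a1 = a0 + int(round(scaled.activity_duration * fs))
        markers += [
            Marker(trial, "trigger_start", cursor),
            Marker(trial, "activity_start", a0),
            Marker(trial, "activity_end", a1),
            Marker(trial, "trigger_end", cursor + n),
        ]
        trial_windows.append((cursor, cursor + n, a0, a1))
        trial_scales.append(scale)
        truth_trials.append(
            {
                "trial": trial,
                "window": [cursor, cursor + n],
                "activity": [a0, a1],
                "duration_scale": scale,
                "activation_jitter": jitter,
            }
        )
        cursor += n

    recording = EMGRecording(
        rate=fs, channels={m: np.concatenate(chunks[m]) for m in MUSCLES}
    )
    truth = {
        "script": script.name,
        "phase_fractions": list(script.phase_fractions),
        "trials": truth_trials,
        "mvc_uv": mvc,
        "envelopes_uv": {m: np.concatenate(envelopes[m]) for m in MUSCLES},
    }
    return recording, markers, truth


def participant_profile(cfg: GeneratorConfig, participant: int) -> dict:
    """Deterministic per-participant anthropometry and MVC scaling."""
    rng = _rng(cfg, 900, participant)
    lengths = tuple(
        float(max(0.05, rng.normal(m, s)))
        for m, s in zip(cfg.lengths_mean, cfg.lengths_sd)
    )
    mvc = {
        m: float(v * np.exp(rng.normal(0.0, cfg.mvc_subject_sd)))
        for m, v in cfg.mvc_uv.items()
    }
    return {"lengths": lengths, "mvc_uv": mvc}


def generate_mvc_recording(
    cfg: GeneratorConfig, muscle: str, mvc: dict[str, float], rng_key: tuple[int, ...]
) -> EMGRecording:
    """A ~3 s maximal-contraction recording for one muscle (the target
    channel near its MVC, the others at light co-contraction)."""
    fs = cfg.emg_rate
    n = int(round(3.0 * fs))
    t = np.arange(n) / fs
    plateau = np.interp(t, [0.0, 0.4, 2.6, 3.0], [0.0, 1.0, 1.0, 0.0])
    channels = {}
    for ci, m in enumerate(MUSCLES):
        rng = _rng(cfg, *rng_key, 50 + ci)
        carrier = rng.normal(size=n)
        carrier = bandpass_filter(carrier, fs)
        carrier /= np.median(np.abs(carrier))
        level = plateau if m == muscle else 0.08 * plateau
        # a unit-median band-limited Gaussian peaks at ~5.5x its median
        # over a 2-3 s stretch (measured once); scale so the *peak* of the
        # recording -- which is what the MVC procedure reads -- lands near
        # the designed MVC
        x = carrier * level * mvc[m] / 5.5
        x = x + rng.normal(scale=cfg.baseline_noise_uv, size=n)
        channels[m] = np.clip(x, -4999.0, 4999.0)
    return EMGRecording(rate=fs, channels=channels)


def generate_cohort(cfg: GeneratorConfig, out_dir) -> dict:
    """Write a full synthetic cohort file tree.

    Layout::

        out_dir/
          manifest.json
          participant_01/
            mvc.csv                  # per-muscle MVC amplitudes (uV)
            mvc_<muscle>.csv         # the MVC recordings they came from
            exercise_1/
              skeleton.csv  emg.csv  markers.csv
            exercise_2/ ...

    Identical (seed, sizes) produce identical trees.  Returns the
    manifest dict (also written as JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "n_participants": cfg.n_participants,
        "n_trials": cfg.n_trials,
        "exercises": {s.name: list(s.phase_fractions) for s in SCRIPTS.values()},
        "participants": [],
    }
    from .emg_pipeline import compute_mvc  # circular-safe local import

    for p in range(cfg.n_participants):
        pdir = out / f"participant_{p + 1:02d}"
        pdir.mkdir(exist_ok=True)
        profile = participant_profile(cfg, p)
        table = default_dh_table(profile["lengths"])
        mvc_measured = {}
        for mi, m in enumerate(MUSCLES):
            rec = generate_mvc_recording(cfg, m, profile["mvc_uv"], (p, 800 + mi))
            write_emg_csv(rec, pdir / f"mvc_{m}.csv")
            mvc_measured[m] = compute_mvc(rec, m)
        write_mvc_csv(MVCTable(mvc_measured), pdir / "mvc.csv")
        entry = {
            "participant": p + 1,
            "lengths_m": list(profile["lengths"]),
            "mvc_design_uv": profile["mvc_uv"],
            "mvc_measured_uv": mvc_measured,
            "exercises": {},
        }
        for ei, script in enumerate(SCRIPTS.values()):
            edir = pdir / script.name
            edir.mkdir(exist_ok=True)
            rec, markers, truth = generate_emg(
                script, cfg, mvc=profile["mvc_uv"], rng_key=(p, ei)
            )
            write_emg_csv(rec, edir / "emg.csv")
            write_markers_csv(markers, edir / "markers.csv")
            t_offset = 0.0
            rng_cam = _rng(cfg, 901, p)
            camera = _camera_isometry(rng_cam)
            all_frames = []
            for trial_info in truth["trials"]:
                scaled = scale_script(script, trial_info["duration_scale"])
                seq, _ = generate_skeleton(
                    scaled,
                    cfg,
                    table=table,
                    rng=_rng(cfg, p, ei, trial_info["trial"], 700),
                    camera=camera,
                )
                for f in seq.frames:
                    all_frames.append(
                        SkeletonFrame(
                            timestamp=f.timestamp + t_offset,
                            spine_shoulder=f.spine_shoulder,
                            hip_center=f.hip_center,
                            shoulder_r=f.shoulder_r,
                            elbow_r=f.elbow_r,
                            wrist_r=f.wrist_r,
                            hand_tip_r=f.hand_tip_r,
                        )
                    )
                t_offset += scaled.duration
            write_skeleton_csv(SkeletonSequence(tuple(all_frames)), edir / "skeleton.csv")
            entry["exercises"][script.name] = {
                "phase_fractions": list(script.phase_fractions),
                "trials": truth["trials"],
            }
        manifest["participants"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
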