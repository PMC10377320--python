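"""Joint-angle recovery from 3D skeleton joint positions.

A depth camera reports 3D positions (metres, camera frame) of the trunk
and right-arm joints at ~30 Hz.  This module converts them into the
six joint angles of the DH arm model in :mod:`limbmanip.arm_kinematics`.

Geometry
--------
A trunk frame is built from ``spine_shoulder`` and ``hip_center``
(z down the spine, x pointing medially from the right shoulder, y = z x x)
so the extracted shoulder angles are invariant to camera placement.
In the trunk frame the elbow sits at ``-L1 * (cos q1 sin q2,
sin q1 sin q2, -cos q2)``: q2 is the elevation of the upper arm
(0 = hanging, pi/2 = horizontal) and q1 selects the elevation plane
(q1 = 0 elevates in the frontal plane, i.e. abduction).

q4 is the elbow flexion angle, ``pi - angle(elbow->shoulder,
elbow->wrist)``, so q4 = 0 at full extension.  q6 is recovered in the
elbow-flexion plane: with the forearm axis f and flexion-plane normal n,
``q6 = atan2(h . f, h . (f x n))`` for hand direction h — in this DH
table the straight-hand (neutral wrist) posture is q6 = pi/2.

q3 (internal rotation) and q5 (pronation/supination) are not observable
from joint positions alone; they are set to 0 and flagged low-confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arm_kinematics import ArmPose, PoseTimeSeries

__all__ = [
    "SkeletonFrame",
    "SkeletonSequence",
    "JOINT_NAMES",
    "segment_lengths",
    "extract_pose",
    "extract_sequence",
    "read_skeleton_csv",
    "write_skeleton_csv",
]

logger = logging.getLogger(__name__)

JOINT_NAMES = (
    "spine_shoulder",
    "hip_center",
    "shoulder_r",
    "elbow_r",
    "wrist_r",
    "hand_tip_r",
)

#: frames whose shoulder-elbow or elbow-wrist distance falls below this
#: are treated as tracking failures.
MIN_SEGMENT_M = 0.01

_DEGENERATE_CROSS = 1e-6


@dataclass(frozen=True)
class SkeletonFrame:
    timestamp: float
    spine_shoulder: np.ndarray
    hip_center: np.ndarray
    shoulder_r: np.ndarray
    elbow_r: np.ndarray
    wrist_r: np.ndarray
    hand_tip_r: np.ndarray

    def point(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def degraded(self) -> bool:
        pts = np.concatenate([self.point(n) for n in JOINT_NAMES])
        if not np.all(np.isfinite(pts)):
            return True
        if np.linalg.norm(self.elbow_r - self.shoulder_r) < MIN_SEGMENT_M:
            return True
        if np.linalg.norm(self.wrist_r - self.elbow_r) < MIN_SEGMENT_M:
            return True
        return False


@dataclass(frozen=True)
class SkeletonSequence:
    frames: tuple[SkeletonFrame, ...]

    def __post_init__(self) -> None:
        t = self.timestamps
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("skeleton timestamps must be strictly increasing")

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)


def segment_lengths(seq: SkeletonSequence) -> tuple[float, float, float]:
    """Median upper-arm, forearm and hand lengths (m) over valid frames."""
    good = [f for f in seq.frames if not f.degraded]
    if not good:
        raise ValueError("no valid skeleton frames")
    L1 = np.median([np.linalg.norm(f.elbow_r - f.shoulder_r) for f in good])
    L2 = np.median([np.linalg.norm(f.wrist_r - f.elbow_r) for f in good])
    L3 = np.median([np.linalg.norm(f.hand_tip_r - f.wrist_r) for f in good])
    return float(L1), float(L2), float(L3)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _trunk_rotation(frame: SkeletonFrame) -> np.ndarray:
    """Columns are the trunk axes (x medial, y, z down) in camera coords."""
    z = _unit(frame.hip_center - frame.spine_shoulder)
    m = frame.spine_shoulder - frame.shoulder_r
    x = m - np.dot(m, z) * z
    x = _unit(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def extract_pose(
    frame: SkeletonFrame, prev_normal: np.ndarray | None = None
) -> tuple[ArmPose, np.ndarray | None]:
    """Recover the arm pose of one frame.

    Returns the pose and the elbow-flexion-plane normal (camera frame),
    which callers thread through as ``prev_normal`` so the wrist-flexion
    sign stays defined when the elbow passes through full extension.
    Joints that cannot be observed are 0 and listed in
    ``pose.low_confidence``.
    """
    if frame.degraded:
        raise ValueError("cannot extract a pose from a degraded frame")

    low_conf = {3, 5}  # axial rotations unobservable from positions
    R = _trunk_rotation(frame)

    # shoulder angles from the upper-arm direction in the trunk frame
    u = R.T @ (frame.elbow_r - frame.shoulder_r)
    u = _unit(u)
    s2 = float(np.hypot(u[0], u[1]))
    q2 = float(np.arctan2(s2, u[2]))
    if s2 > _DEGENERATE_CROSS:
        q1 = float(np.arctan2(-u[1], -u[0]))
    else:
        q1 = 0.0  # hanging arm: elevation plane undefined
        low_conf.add(1)

    # elbow flexion (0 = fully extended)
    ua = frame.shoulder_r - frame.elbow_r
    fa = frame.wrist_r - frame.elbow_r
    cos4 = np.dot(_unit(ua), _unit(fa))
    q4 = float(np.pi - np.arccos(np.clip(cos4, -1.0, 1.0)))

    # wrist flexion in the elbow-flexion plane
    n = np.cross(ua, fa)
    n_norm = np.linalg.norm(n)
    if n_norm < _DEGENERATE_CROSS:
        n = prev_normal
    else:
        n = n / n_norm
    f = _unit(frame.wrist_r - frame.elbow_r)
    h = _unit(frame.hand_tip_r - frame.wrist_r)
    if n is None:
        q6 = float(np.pi / 2)  # neutral; no plane to sign against
        low_conf.add(6)
        normal_out = None
    else:
        b = np.cross(f, n)
        q6 = float(np.arctan2(np.dot(h, f), np.dot(h, b)))
        normal_out = n

    pose = ArmPose((q1, q2, 0.0, q4, 0.0, q6), frozenset(low_conf))
    return pose, normal_out


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    h = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        out[i] = np.median(x[max(0, i - h) : i + h + 1])
    return out


def extract_sequence(
    seq: SkeletonSequence, smooth_window: int = 5
) -> PoseTimeSeries:
    """Per-frame pose extraction over a sequence.

    Degraded frames carry the last valid pose forward (flagged with the
    sentinel 0 in ``low_confidence``); leading
    degraded frames are back-filled from the first valid one.  An optional
    moving-median filter (``smooth_window`` frames, default 5; 1 disables)
    suppresses skeleton jitter on the extracted angles.
    """
    if len(seq) == 0:
        raise ValueError("empty skeleton sequence")
    poses: list[ArmPose | None] = []
    normal = None
    n_degraded = 0
    for frame in seq.frames:
        if frame.degraded:
            n_degraded += 1
            if poses and poses[-1] is not None:
                prev = poses[-1]
                poses.append(ArmPose(prev.q, prev.low_confidence | {0}))
            else:
                poses.append(None)  # back-filled below
        else:
            pose, normal = extract_pose(frame, normal)
            poses.append(pose)
    first_valid = next((p for p in poses if p is not None), None)
    if first_valid is None:
        raise ValueError("all skeleton frames are degraded")
    poses = [
        p if p is not None else ArmPose(first_valid.q, first_valid.low_confidence | {0})
        for p in poses
    ]
    if n_degraded:
        logger.warning("carried %d degraded skeleton frames forward", n_degraded)

    if smooth_window > 1 and len(poses) > 1:
        q = np.array([p.q for p in poses])
        for j in range(6):
            q[:, j] = _moving_median(q[:, j], smooth_window)
        poses = [
            ArmPose(tuple(q[i]), poses[i].low_confidence) for i in range(len(poses))
        ]
    return PoseTimeSeries(seq.timestamps, tuple(poses))


def write_skeleton_csv(seq: SkeletonSequence, path) -> None:
    """Columns: time_s then <joint>_{x,y,z} per joint, metres."""
    data = {"time_s": seq.timestamps}
    for name in JOINT_NAMES:
        pts = np.array([f.point(name) for f in seq.frames])
        for k, ax in enumerate("xyz"):
            data[f"{name}_{ax}"] = pts[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_skeleton_csv(path) -> SkeletonSequence:
    df = pd.read_csv(path)
    expected = ["time_s"] + [f"{n}_{ax}" for n in JOINT_NAMES for ax in "xyz"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path)}: missing skeleton columns {missing}")
    frames = []
    for _, row in df.iterrows():
        kwargs = {
            name: np.array([row[f"{name}_{ax}"] for ax in "xyz"], dtype=float)
            for name in JOINT_NAMES
        }
        frames.append(SkeletonFrame(timestamp=float(row["time_s"]), **kwargs))
    return SkeletonSequence(tuple(frames))
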