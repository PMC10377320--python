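"""Denavit-Hartenberg kinematics of a 6-DOF right-arm model.

The arm is modelled as a serial chain of three rigid segments (upper arm
L1, forearm L2, hand L3) driven by six revolute joints:

=====  =============================  =========
joint  motion                         symbol
=====  =============================  =========
1      shoulder abduction/adduction   q1
2      shoulder flexion/extension     q2
3      internal/external rotation     q3
4      elbow flexion/extension        q4
5      forearm pronation/supination   q5
6      wrist flexion/extension        q6
=====  =============================  =========

Standard (distal) DH convention is used throughout: each row contributes
``Rz(theta) @ Tz(d) @ Tx(a) @ Rx(alpha)`` with ``theta = theta_offset + q``.
Units are metres and radians.  The geometric Jacobian stacks linear rows
above angular rows; scalar manipulability indices in
:mod:`limbmanip.manipulability` depend on that ordering being fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DHRow",
    "DHTable",
    "ArmPose",
    "PoseTimeSeries",
    "default_dh_table",
    "dh_transform",
    "forward_kinematics",
    "geometric_jacobian",
]

#: default segment lengths in metres (upper arm, forearm, hand) --
#: plausible adult values, overridable everywhere a DHTable is built.
DEFAULT_LENGTHS = (0.30, 0.25, 0.18)


@dataclass(frozen=True)
class DHRow:
    """One standard-DH row; the joint variable is added to ``theta_offset``."""

    theta_offset: float
    alpha: float
    a: float
    d: float
    joint_index: int

    def __post_init__(self) -> None:
        if not (1 <= self.joint_index <= 6):
            raise ValueError(f"joint_index must be in 1..6, got {self.joint_index}")
        for name in ("theta_offset", "alpha", "a", "d"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"DHRow field {name!r} must be finite")


@dataclass(frozen=True)
class DHTable:
    """Six DH rows plus the segment lengths they embed."""

    rows: tuple[DHRow, ...]
    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.rows) != 6:
            raise ValueError(f"DHTable needs exactly 6 rows, got {len(self.rows)}")
        driven = sorted(r.joint_index for r in self.rows)
        if driven != [1, 2, 3, 4, 5, 6]:
            raise ValueError("each of q1..q6 must drive exactly one row")
        if any(L <= 0 for L in self.lengths):
            raise ValueError(f"segment lengths must be positive, got {self.lengths}")

    @property
    def reach(self) -> float:
        """Maximum endpoint distance from the shoulder: L1 + L2 + L3."""
        return float(sum(self.lengths))


@dataclass(frozen=True)
class ArmPose:
    """Joint angles q1..q6 in radians."""

    q: tuple[float, float, float, float, float, float]
    low_confidence: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.q) != 6:
            raise ValueError("ArmPose needs 6 joint angles")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("joint angles must be finite")

    @classmethod
    def from_array(cls, q: Sequence[float], low_confidence: Sequence[int] = ()) -> "ArmPose":
        return cls(tuple(float(v) for v in q), frozenset(low_confidence))


@dataclass(frozen=True)
class PoseTimeSeries:
    """A timed sequence of arm poses (timestamps strictly increasing, seconds)."""

    timestamps: np.ndarray
    poses: tuple[ArmPose, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", t)
        if len(t) != len(self.poses):
            raise ValueError("timestamps and poses must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.poses)

    def angles(self) -> np.ndarray:
        """(n, 6) array of joint angles."""
        return np.array([p.q for p in self.poses], dtype=float)


def default_dh_table(
    lengths: tuple[float, float, float] = DEFAULT_LENGTHS,
) -> DHTable:
    """The 6-DOF right-arm DH table.

    Joint 2's theta is driven by q2 (the published table repeats q3 on
    rows 2 and 3; a chain with six distinct DOF requires q2 there).
    """
    L1, L2, L3 = lengths
    half_pi = np.pi / 2.0
    rows = (
        DHRow(0.0, half_pi, 0.0, 0.0, 1),
        DHRow(0.0, half_pi, 0.0, 0.0, 2),
        DHRow(0.0, half_pi, 0.0, -L1, 3),
        DHRow(0.0, -half_pi, 0.0, 0.0, 4),
        DHRow(0.0, -half_pi, 0.0, -L2, 5),
        DHRow(0.0, 0.0, L3, 0.0, 6),
    )
    return DHTable(rows, (float(L1), float(L2), float(L3)))


def dh_transform(row: DHRow, q_value: float) -> np.ndarray:
    """Homogeneous transform Rz(theta)·Tz(d)·Tx(a)·Rx(alpha), theta = offset + q."""
    if not np.isfinite(q_value):
        raise ValueError("joint value must be finite")
    theta = row.theta_offset + q_value
    ct, st = np.cos(theta), np.sin(theta)
    ca, sa = np.cos(row.alpha), np.sin(row.alpha)
    return np.array(
        [
            [ct, -st * ca, st * sa, row.a * ct],
            [st, ct * ca, -ct * sa, row.a * st],
            [0.0, sa, ca, row.d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def forward_kinematics(
    table: DHTable, pose: ArmPose
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward kinematics of the whole chain.

    Returns
    -------
    endpoint : (4, 4) ndarray
        Homogeneous transform of the hand-tip frame in the shoulder frame.
    frames : list of 7 (4, 4) ndarrays
        ``frames[i]`` is the pose of frame i (frame 0 is the base identity);
        needed to build the geometric Jacobian.  Frame origins 3, 5 and 6
        are the elbow, wrist and hand tip.
    """
    T = np.eye(4)
    frames = [T]
    for row in table.rows:
        T = T @ dh_transform(row, pose.q[row.joint_index - 1])
        frames.append(T)
    return frames[-1], frames


def geometric_jacobian(table: DHTable, pose: ArmPose) -> np.ndarray:
    """6x6 geometric Jacobian; rows 1-3 linear (m/s per rad/s), rows 4-6 angular.

    All six joints are revolute, so column i is
    ``[z_{i-1} x (p_e - p_{i-1}); z_{i-1}]`` with axes and origins taken
    from the intermediate forward-kinematics frames.
    """
    endpoint, frames = forward_kinematics(table, pose)
    p_e = endpoint[:3, 3]
    J = np.empty((6, 6))
    for i in range(6):
        z = frames[i][:3, 2]
        p = frames[i][:3, 3]
        J[:3, i] = np.cross(z, p_e - p)
        J[3:, i] = z
    return J
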