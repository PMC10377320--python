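"""Skeleton-to-joint-angle recovery, validated by forward-kinematics round trips."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from limbmanip.arm_kinematics import ArmPose, default_dh_table, forward_kinematics
from limbmanip.pose_extraction import (
    SkeletonFrame,
    SkeletonSequence,
    extract_pose,
    extract_sequence,
    read_skeleton_csv,
    segment_lengths,
    write_skeleton_csv,
)
from limbmanip.synthetic_data import EXERCISE_1, GeneratorConfig, generate_skeleton

TRUNK = dict(
    spine_shoulder=np.array([0.18, 0.0, -0.02]),
    hip_center=np.array([0.18, 0.0, 0.53]),
    shoulder_r=np.zeros(3),
)


def frame_from_pose(q, table=None, timestamp=0.0):
    """Render one skeleton frame through the forward kinematics."""
    table = table or default_dh_table()
    _, chain = forward_kinematics(table, ArmPose.from_array(q))
    return SkeletonFrame(
        timestamp=timestamp,
        elbow_r=chain[3][:3, 3],
        wrist_r=chain[5][:3, 3],
        hand_tip_r=chain[6][:3, 3],
        **TRUNK,
    )


def apply_isometry(frame, R, t):
    kw = {
        name: R @ frame.point(name) + t
        for name in (
            "spine_shoulder",
            "hip_center",
            "shoulder_r",
            "elbow_r",
            "wrist_r",
            "hand_tip_r",
        )
    }
    return SkeletonFrame(timestamp=frame.timestamp, **kw)


class TestSegmentLengths:
    def test_collinear_distances(self):
        f = SkeletonFrame(
            timestamp=0.0,
            spine_shoulder=np.array([0.2, 0, 0]),
            hip_center=np.array([0.2, 0, 0.5]),
            shoulder_r=np.zeros(3),
            elbow_r=np.array([0, -0.3, 0]),
            wrist_r=np.array([0, -0.55, 0]),
            hand_tip_r=np.array([0, -0.73, 0]),
        )
        L = segment_lengths(SkeletonSequence((f,)))
        assert L == pytest.approx((0.30, 0.25, 0.18))

    def test_invariant_under_isometry(self, rng):
        f = frame_from_pose([0.2, 0.9, 0, 1.1, 0, 1.4])
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        t = rng.normal(size=3)
        seq_a = SkeletonSequence((f,))
        seq_b = SkeletonSequence((apply_isometry(f, R, t),))
        assert segment_lengths(seq_a) == pytest.approx(segment_lengths(seq_b))

    def test_median_robust_to_noise(self, rng):
        frames = []
        for i in range(100):
            f = frame_from_pose([0.2, 0.9, 0, 1.1, 0, 1.4], timestamp=i / 30)
            noisy = {
                n: f.point(n) + rng.normal(scale=0.005, size=3)
                for n in (
                    "spine_shoulder", "hip_center", "shoulder_r",
                    "elbow_r", "wrist_r", "hand_tip_r",
                )
            }
            frames.append(SkeletonFrame(timestamp=f.timestamp, **noisy))
        L = segment_lengths(SkeletonSequence(tuple(frames)))
        assert L == pytest.approx((0.30, 0.25, 0.18), abs=0.01)

    def test_no_valid_frames(self):
        f = SkeletonFrame(
            timestamp=0.0,
            spine_shoulder=np.zeros(3),
            hip_center=np.array([0, 0, 0.5]),
            shoulder_r=np.zeros(3),
            elbow_r=np.full(3, 1e-4),  # collapsed arm
            wrist_r=np.full(3, 2e-4),
            hand_tip_r=np.full(3, 3e-4),
        )
        with pytest.raises(ValueError):
            segment_lengths(SkeletonSequence((f,)))


class TestExtractPose:
    def test_collinear_arm_is_full_extension(self):
        pose, _ = extract_pose(frame_from_pose([0.0, 0.9, 0, 0.0, 0, 1.2]))
        assert pose.q[3] == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_elbow(self):
        pose, _ = extract_pose(frame_from_pose([0.0, 0.9, 0, np.pi / 2, 0, 1.2]))
        assert pose.q[3] == pytest.approx(np.pi / 2, abs=1e-9)

    def test_axial_joints_flagged_low_confidence(self):
        pose, _ = extract_pose(frame_from_pose([0.1, 0.8, 0, 1.0, 0, 1.3]))
        assert {3, 5} <= set(pose.low_confidence)
        assert pose.q[2] == 0.0 and pose.q[4] == 0.0

    def test_fk_round_trip(self, rng):
        table = default_dh_table()
        for _ in range(30):
            q = rng.uniform(-1.2, 1.2, 6)
            q[1] = rng.uniform(0.15, 1.4)  # observable elevation plane
            q[2] = q[4] = 0.0
            q[3] = rng.uniform(0.1, 2.4)
            pose, _ = extract_pose(frame_from_pose(q, table))
            got = np.array(pose.q)
            assert np.allclose(got[[0, 1, 3, 5]], q[[0, 1, 3, 5]], atol=1e-6)

    def test_round_trip_endpoint(self, rng):
        table = default_dh_table()
        q = np.array([0.4, 0.9, 0.0, 1.3, 0.0, 1.9])
        pose, _ = extract_pose(frame_from_pose(q, table))
        e1, _ = forward_kinematics(table, ArmPose.from_array(q))
        e2, _ = forward_kinematics(table, pose)
        assert np.linalg.norm(e1[:3, 3] - e2[:3, 3]) < 1e-6

    def test_interjoint_angles_camera_invariant(self, rng):
        q = np.array([0.3, 0.7, 0.0, 1.1, 0.0, 2.0])
        f = frame_from_pose(q)
        R = Rotation.random(random_state=np.random.RandomState(11)).as_matrix()
        g = apply_isometry(f, R, rng.normal(size=3))
        pa, _ = extract_pose(f)
        pb, _ = extract_pose(g)
        assert pa.q[3] == pytest.approx(pb.q[3], abs=1e-9)
        assert pa.q[5] == pytest.approx(pb.q[5], abs=1e-9)

    def test_degraded_frame_rejected(self):
        f = frame_from_pose([0.1, 0.8, 0, 1.0, 0, 1.3])
        bad = SkeletonFrame(
            timestamp=0.0,
            spine_shoulder=f.spine_shoulder,
            hip_center=f.hip_center,
            shoulder_r=f.shoulder_r,
            elbow_r=f.shoulder_r + 1e-4,  # collapsed upper arm
            wrist_r=f.wrist_r,
            hand_tip_r=f.hand_tip_r,
        )
        assert bad.degraded
        with pytest.raises(ValueError):
            extract_pose(bad)


class TestExtractSequence:
    def test_constant_frames_constant_poses(self):
        f = frame_from_pose([0.2, 0.8, 0, 1.2, 0, 1.5])
        frames = tuple(
            SkeletonFrame(
                timestamp=i / 30.0,
                **{n: f.point(n) for n in (
                    "spine_shoulder", "hip_center", "shoulder_r",
                    "elbow_r", "wrist_r", "hand_tip_r")},
            )
            for i in range(10)
        )
        out = extract_sequence(SkeletonSequence(frames))
        assert np.ptp(out.angles(), axis=0) == pytest.approx(np.zeros(6), abs=1e-12)

    def test_degraded_frames_carry_forward(self):
        good = frame_from_pose([0.2, 0.8, 0, 1.2, 0, 1.5])
        bad = SkeletonFrame(
            timestamp=1 / 30.0,
            spine_shoulder=good.spine_shoulder,
            hip_center=good.hip_center,
            shoulder_r=good.shoulder_r,
            elbow_r=good.shoulder_r + 1e-4,
            wrist_r=good.wrist_r,
            hand_tip_r=good.hand_tip_r,
        )
        frames = (good, bad)
        out = extract_sequence(SkeletonSequence(frames), smooth_window=1)
        assert np.allclose(out.angles()[0], out.angles()[1])
        assert 0 in out.poses[1].low_confidence  # carried-forward sentinel

    def test_scripted_round_trip_exact_without_noise(self):
        cfg = GeneratorConfig(seed=5, joint_noise_m=0.0, duration_jitter=0.0)
        seq, truth = generate_skeleton(EXERCISE_1, cfg)
        out = extract_sequence(seq, smooth_window=1)
        err = np.abs(out.angles() - truth.angles())
        assert err[:, [0, 1, 3, 5]].max() < 1e-6

    def test_noisy_q4_rmse_under_three_degrees(self):
        cfg = GeneratorConfig(seed=5, joint_noise_m=0.005, duration_jitter=0.0)
        seq, truth = generate_skeleton(EXERCISE_1, cfg)
        out = extract_sequence(seq)  # default 5-frame median smoothing
        err = out.angles()[:, 3] - truth.angles()[:, 3]
        assert np.degrees(np.sqrt(np.mean(err**2))) < 3.0


def test_skeleton_csv_round_trip(tmp_path, rng):
    cfg = GeneratorConfig(seed=2, n_trials=1)
    seq, _ = generate_skeleton(EXERCISE_1, cfg)
    path = tmp_path / "skeleton.csv"
    write_skeleton_csv(seq, path)
    back = read_skeleton_csv(path)
    assert len(back) == len(seq)
    assert np.allclose(back.timestamps, seq.timestamps, atol=1e-6)
    assert np.allclose(back.frames[3].wrist_r, seq.frames[3].wrist_r, atol=1e-5)


def test_skeleton_csv_missing_column(tmp_path):
    import pandas as pd

    pd.DataFrame({"time_s": [0.0]}).to_csv(tmp_path / "bad.csv", index=False)
    with pytest.raises(ValueError, match="missing skeleton columns"):
        read_skeleton_csv(tmp_path / "bad.csv")
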