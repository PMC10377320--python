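"""Manipulability of single arm poses.

Builds the 6-DOF right-arm model with default segment lengths and
evaluates the three indices at a few characteristic postures.  KMI is
the volume-like Yoshikawa measure (0 at a singularity), Id the Jacobian
condition number (blows up near singularities) and LCI its reciprocal
in [0, 1] (1 = isotropic, 0 = singular).
"""

import numpy as np

from limbmanip import ArmPose, default_dh_table, indices_for_pose

table = default_dh_table()  # L1=0.30, L2=0.25, L3=0.18 m
half_pi = np.pi / 2

poses = {
    "arm hanging, slight elbow bend": [0, 0.10, 0, 0.12, 0, half_pi],
    "abducted 90 deg, elbow straight": [0, half_pi, 0, 0.0, 0, half_pi],
    "abducted, elbow at 90 deg": [0, half_pi, 0, half_pi, 0, half_pi],
    "abducted, elbow fully flexed": [0, half_pi, 0, 2.2, 0, half_pi],
    "extended arm + wrist flexed": [0, half_pi, 0, 0.0, 0, half_pi + 0.9],
}

print(f"{'posture':34s} {'KMI':>10s} {'Id':>10s} {'LCI':>8s}")
for name, q in poses.items():
    idx = indices_for_pose(table, ArmPose.from_array(q))
    dex = "inf" if np.isinf(idx.dexterity) else f"{idx.dexterity:10.1f}"
    print(f"{name:34s} {idx.kmi:10.3e} {dex:>10s} {idx.lci:8.4f}")

print(
    "\nThe straight-elbow postures are singular (KMI ~ 0, LCI = 0): the"
    "\nhand cannot move along the arm axis. Mid-flexion maximises the"
    "\nindices; wrist posture barely changes them."
)
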