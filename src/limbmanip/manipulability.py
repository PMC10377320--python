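"""Scalar manipulability indices of the arm Jacobian.

Three indices are computed from the 6x6 geometric Jacobian ``J``:

* **KMI** (kinematic manipulability index, Yoshikawa):
  ``w = sqrt(det(J @ J.T))``, the product of singular values.  Zero at a
  singularity.  The squared variant ``det(J @ J.T)`` is available via
  ``definition="det"``.
* **Dexterity index** ``Id = ||J|| * ||J^-1||``: the spectral-norm
  condition number sigma_max / sigma_min; +inf at a singularity.
* **LCI** (local conditioning index): ``1 / Id`` in [0, 1]; 1 means an
  isotropic (maximally comfortable) configuration, 0 a singular one.

The Jacobian mixes metres and radians; indices are reported in raw model
units with no characteristic-length normalisation, so absolute KMI values
are comparable only within one model/segment-length choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm_kinematics import ArmPose, DHTable, PoseTimeSeries, geometric_jacobian

__all__ = [
    "SINGULARITY_RTOL",
    "ManipulabilityIndices",
    "IndexTimeSeries",
    "kmi",
    "dexterity_index",
    "lci",
    "indices_for_pose",
    "indices_over_trajectory",
    "resample_series",
]

#: relative rank tolerance: J is treated as singular when
#: sigma_min < SINGULARITY_RTOL * sigma_max.
SINGULARITY_RTOL = 1e-12


@dataclass(frozen=True)
class ManipulabilityIndices:
    kmi: float
    dexterity: float
    lci: float

    @property
    def singular(self) -> bool:
        return not np.isfinite(self.dexterity)


@dataclass(frozen=True)
class IndexTimeSeries:
    """Per-frame KMI and LCI aligned to a common timeline (seconds)."""

    timestamps: np.ndarray
    kmi: np.ndarray
    lci: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        k = np.asarray(self.kmi, dtype=float)
        c = np.asarray(self.lci, dtype=float)
        if not (len(t) == len(k) == len(c)):
            raise ValueError("timestamps, kmi and lci must have equal length")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "kmi", k)
        object.__setattr__(self, "lci", c)

    def __len__(self) -> int:
        return len(self.timestamps)


def _check_jacobian(J: np.ndarray) -> np.ndarray:
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian entries must be finite")
    return J


def kmi(J: np.ndarray, definition: str = "yoshikawa_sqrt") -> float:
    """Kinematic manipulability index of ``J``.

    ``definition="yoshikawa_sqrt"`` (default) returns sqrt(det(J J^T)),
    equal to the product of singular values; ``"det"`` returns det(J J^T)
    itself.  For the square Jacobian sqrt(det(J J^T)) = |det J|, which is
    how it is evaluated: forming J J^T first would square the condition
    number and cost digits (and its determinant can round off negative).
    """
    J = _check_jacobian(J)
    if J.shape[0] != J.shape[1]:
        raise ValueError("kmi expects a square Jacobian")
    w = abs(float(np.linalg.det(J)))
    if definition == "yoshikawa_sqrt":
        return w
    if definition == "det":
        return w * w
    raise ValueError(f"unknown kmi definition {definition!r}")


def dexterity_index(J: np.ndarray) -> float:
    """Spectral-norm condition number sigma_max / sigma_min (+inf if singular)."""
    J = _check_jacobian(J)
    sv = np.linalg.svd(J, compute_uv=False)
    smax, smin = sv[0], sv[-1]
    if smax == 0.0 or smin < SINGULARITY_RTOL * smax:
        return float("inf")
    return float(smax / smin)


def lci(J: np.ndarray) -> float:
    """Local conditioning index sigma_min / sigma_max in [0, 1]; 0 if singular."""
    J = _check_jacobian(J)
    sv = np.linalg.svd(J, compute_uv=False)
    smax, smin = sv[0], sv[-1]
    if smax == 0.0 or smin < SINGULARITY_RTOL * smax:
        return 0.0
    return float(smin / smax)


def indices_for_pose(
    table: DHTable, pose: ArmPose, definition: str = "yoshikawa_sqrt"
) -> ManipulabilityIndices:
    J = geometric_jacobian(table, pose)
    return ManipulabilityIndices(
        kmi=kmi(J, definition), dexterity=dexterity_index(J), lci=lci(J)
    )


def indices_over_trajectory(
    table: DHTable, series: PoseTimeSeries, definition: str = "yoshikawa_sqrt"
) -> IndexTimeSeries:
    """KMI and LCI per frame of a pose time series; timestamps preserved."""
    if len(series) == 0:
        raise ValueError("empty pose series")
    k = np.empty(len(series))
    c = np.empty(len(series))
    for i, pose in enumerate(series.poses):
        J = geometric_jacobian(table, pose)
        k[i] = kmi(J, definition)
        c[i] = lci(J)
    return IndexTimeSeries(series.timestamps.copy(), k, c)


def resample_series(series: IndexTimeSeries, target_length: int) -> IndexTimeSeries:
    """Resample onto a uniform grid spanning [first, last] timestamp.

    Linear interpolation; endpoints are preserved exactly and values
    cannot overshoot the input range.  Used to align the 30 Hz skeleton
    timeline with the 1500 Hz sEMG timeline.
    """
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    if len(series) < 2:
        raise ValueError("need at least 2 samples to resample")
    t = series.timestamps
    grid = np.linspace(t[0], t[-1], target_length)
    return IndexTimeSeries(
        grid,
        np.interp(grid, t, series.kmi),
        np.interp(grid, t, series.lci),
    )


def write_index_tsv(series: IndexTimeSeries, path) -> None:
    """Write an index series as TSV with columns time_s, kmi, lci."""
    import pandas as pd

    pd.DataFrame(
        {"time_s": series.timestamps, "kmi": series.kmi, "lci": series.lci}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
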