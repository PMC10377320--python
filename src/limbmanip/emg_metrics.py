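"""Time-domain sEMG effort features and their per-phase aggregation.

Four window features are computed on the band-passed (signed, microvolt)
signal of each exercise phase:

* ``rms``  — root mean square, sqrt(mean(x_i^2)): mean signal magnitude.
* ``mav``  — mean absolute value, mean(|x_i|): rectified amplitude.
* ``wl``   — waveform length, sum(|x_{i+1} - x_i|): amplitude +
  frequency content accumulated over the window.
* ``ssc``  — slope-sign changes: count of i with
  (x_i - x_{i-1}) * (x_i - x_{i+1}) >= threshold; the 100 uV default
  threshold suppresses baseline-noise slope reversals.

Aggregation is two-level, matching how cohort statistics are reported:
first the mean over a participant's trials, then mean +- sd (sample,
n-1) across participants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emg_pipeline import TrialSegmentation, TrialWindow

__all__ = [
    "METRICS",
    "SSC_THRESHOLD_UV",
    "rms",
    "mav",
    "wl",
    "ssc",
    "metrics_for_window",
    "metrics_per_phase",
    "aggregate",
]

METRICS = ("rms", "mav", "wl", "ssc")

#: default slope-sign-change threshold in microvolts.
SSC_THRESHOLD_UV = 100.0


def _window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D window")
    return x


def rms(x) -> float:
    x = _window(x)
    if len(x) == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x * x)))


def mav(x) -> float:
    x = _window(x)
    if len(x) == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def wl(x) -> float:
    x = _window(x)
    if len(x) < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def ssc(x, threshold: float = SSC_THRESHOLD_UV) -> int:
    x = _window(x)
    if len(x) < 3:
        raise ValueError("slope-sign change needs at least 3 samples")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return int(np.count_nonzero(prod >= threshold))


def metrics_for_window(x, threshold: float = SSC_THRESHOLD_UV) -> dict[str, float]:
    """All four features on one window."""
    return {
        "rms": rms(x),
        "mav": mav(x),
        "wl": wl(x),
        "ssc": float(ssc(x, threshold)),
    }


def metrics_per_phase(
    trial: np.ndarray,
    seg: TrialSegmentation,
    window: TrialWindow,
    threshold: float = SSC_THRESHOLD_UV,
    muscle: str | None = None,
    include_whole: bool = True,
) -> pd.DataFrame:
    """Features of each exercise phase of one trial.

    ``trial`` is the band-passed signal of the *whole recording* (same
    sample indexing as the segmentation), signed and in microvolts so
    the SSC threshold keeps its physical meaning.  Rows: one per phase
    (named ``phase_1`` ...) plus ``whole`` over the full activity window.
    """
    rows = []
    phases = seg.phase_windows(window)
    spans = [(f"phase_{i + 1}", s, e) for i, (s, e) in enumerate(phases)]
    if include_whole:
        spans.append(("whole", window.activity_start, window.activity_end))
    for name, s, e in spans:
        if not (0 <= s < e <= len(trial)):
            raise ValueError(f"{name} window [{s},{e}) invalid for trial length {len(trial)}")
        feats = metrics_for_window(trial[s:e], threshold)
        for metric, value in feats.items():
            rows.append(
                {
                    "metric": metric,
                    "muscle": muscle,
                    "phase": name,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def aggregate(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Two-level cohort aggregation of per-trial metric values.

    Input needs columns ``participant, metric, muscle, phase, value``
    (one row per trial).  Trials are averaged within each participant
    first; the returned table carries the across-participant ``mean``,
    sample ``sd`` (0 when a single participant) and ``n`` participants
    per (metric, muscle, phase) cell.
    """
    required = {"participant", "metric", "muscle", "phase", "value"}
    missing = required - set(per_trial.columns)
    if missing:
        raise ValueError(f"aggregate: missing columns {sorted(missing)}")
    if per_trial.empty:
        raise ValueError("aggregate: empty table")
    per_participant = (
        per_trial.groupby(["participant", "metric", "muscle", "phase"], as_index=False)[
            "value"
        ].mean()
    )
    out = (
        per_participant.groupby(["metric", "muscle", "phase"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out


def participant_means(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Per-participant trial means — the sampling unit for the statistics."""
    return (
        per_trial.groupby(["participant", "metric", "muscle", "phase"], as_index=False)[
            "value"
        ].mean()
    )


def write_metrics_tsv(table: pd.DataFrame, path) -> None:
    """Aggregate table as TSV: metric, muscle, phase, mean, sd, n."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
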