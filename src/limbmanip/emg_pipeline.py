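"""Surface-EMG preprocessing: filter, rectify, envelope, MVC-normalise,
segment into trials and resample them to a common length.

The processing order is fixed::

    bandpass (20-300 Hz Butterworth, zero phase)
      -> full-wave rectification
      -> running-median envelope (3500-bin window, coerced odd)
      -> division by the muscle's maximum voluntary contraction (MVC)

Trial boundaries arrive as marker files (trigger start/end for the whole
trial, activity start/end for the movement inside it); automatic onset
detection is deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "MUSCLES",
    "EMGRecording",
    "MVCTable",
    "Marker",
    "TrialWindow",
    "TrialSegmentation",
    "bandpass_filter",
    "rectify",
    "envelope",
    "mvc_normalize",
    "compute_mvc",
    "segment_trials",
    "resample_trials",
    "read_emg_csv",
    "write_emg_csv",
    "read_markers_csv",
    "write_markers_csv",
    "read_mvc_csv",
    "write_mvc_csv",
]

logger = logging.getLogger(__name__)

#: recorded muscles: flexor carpi ulnaris, extensor carpi ulnaris,
#: biceps brachii, deltoideus medius.
MUSCLES = ("fcu", "ecu", "bb", "dm")

#: default band edges (Hz) and overall filter order of the Butterworth
#: band-pass applied before any feature extraction.
BAND_HZ = (20.0, 300.0)
FILTER_ORDER = 8

#: default running-median envelope window in samples at 1500 Hz; the
#: published 3500 is even and is coerced to 3501 at call time.
ENVELOPE_WINDOW = 3500

SENSOR_RANGE_UV = 5000.0  # +-5 mV input range


@dataclass(frozen=True)
class EMGRecording:
    """Multichannel sEMG in microvolts at a common sampling rate."""

    rate: float
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        for name, x in self.channels.items():
            x = np.asarray(x, dtype=float)
            if not np.all(np.isfinite(x)):
                raise ValueError(f"channel {name!r} has non-finite samples")
            if len(x) and np.max(np.abs(x)) > SENSOR_RANGE_UV:
                raise ValueError(
                    f"channel {name!r} exceeds the +-{SENSOR_RANGE_UV:.0f} uV sensor range"
                )
            self.channels[name] = x

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class MVCTable:
    """Per-muscle maximum voluntary contraction amplitudes (microvolts)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = {m: v for m, v in self.values.items() if not v > 0}
        if bad:
            raise ValueError(f"MVC values must be positive: {bad}")

    def __getitem__(self, muscle: str) -> float:
        return self.values[muscle]


@dataclass(frozen=True)
class Marker:
    trial_id: int
    kind: str  # trigger_start | trigger_end | activity_start | activity_end
    sample_index: int


@dataclass(frozen=True)
class TrialWindow:
    """Half-open sample windows [start, end) of one trial."""

    trial_id: int
    start: int
    end: int
    activity_start: int
    activity_end: int

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError("trial window must be non-empty")
        if not (self.start <= self.activity_start < self.activity_end <= self.end):
            raise ValueError("activity window must lie inside the trial window")


@dataclass(frozen=True)
class TrialSegmentation:
    trials: tuple[TrialWindow, ...]
    phase_fractions: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = -1
        for w in self.trials:
            if w.start <= prev_end:
                raise ValueError("trial windows must be ordered and non-overlapping")
            prev_end = w.end - 1
        fr = self.phase_fractions
        if fr and not (
            all(0.0 < f < 1.0 for f in fr) and all(a < b for a, b in zip(fr, fr[1:]))
        ):
            raise ValueError("phase fractions must be strictly increasing in (0,1)")

    def phase_windows(self, trial: TrialWindow) -> list[tuple[int, int]]:
        """Split a trial's activity window into per-phase sample windows."""
        a, b = trial.activity_start, trial.activity_end
        cuts = [a] + [a + int(round(f * (b - a))) for f in self.phase_fractions] + [b]
        return [(s, e) for s, e in zip(cuts, cuts[1:])]


def bandpass_filter(
    x: np.ndarray,
    rate: float,
    band: tuple[float, float] = BAND_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    ``order`` is the overall filter order (an 8th-order band-pass has 4
    pole pairs per edge); forward-backward application keeps activation
    onsets aligned with the trial markers at the cost of squaring the
    magnitude response.
    """
    x = np.asarray(x, dtype=float)
    if rate <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {band[1]} Hz band edge"
        )
    if len(x) <= 3 * order:
        raise ValueError("signal too short to filter")
    sos = sps.butter(order // 2, band, btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def _nearest_rank_median(seg: np.ndarray) -> float:
    # rank ceil(m/2) of m samples; equals the middle element for odd m
    k = (len(seg) + 1) // 2 - 1
    return float(np.partition(seg, k)[k])


def envelope(x: np.ndarray, window: int = ENVELOPE_WINDOW) -> np.ndarray:
    """Running-median envelope of a rectified signal.

    Even windows are coerced to the next odd length (a centred window
    needs one).  Edges use a shrinking window: the nearest-rank median of
    whatever samples fall inside, which avoids padding artefacts at trial
    boundaries.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0:
        logger.info("even envelope window %d coerced to %d", window, window + 1)
        window += 1
    if window > len(x):
        raise ValueError(f"envelope window {window} exceeds signal length {len(x)}")
    if window == 1:
        return x.copy()
    out = (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    h = window // 2
    for i in range(min(h, len(x))):
        out[i] = _nearest_rank_median(x[: i + h + 1])
        out[-(i + 1)] = _nearest_rank_median(x[len(x) - (i + h + 1) :])
    return out


def mvc_normalize(env: np.ndarray, mvc: float) -> np.ndarray:
    """Express an envelope as a fraction of the muscle's MVC."""
    if not mvc > 0:
        raise ValueError(f"MVC must be positive, got {mvc}")
    return np.asarray(env, dtype=float) / mvc


def compute_mvc(
    recording: EMGRecording, muscle: str, band: tuple[float, float] = BAND_HZ
) -> float:
    """MVC amplitude: peak of the rectified, band-passed MVC recording.

    A zero result is returned as-is; callers must treat it as invalid for
    normalisation (MVCTable refuses non-positive values).
    """
    x = recording.channels[muscle]
    if len(x) == 0:
        raise ValueError("empty MVC recording")
    filtered = bandpass_filter(x, recording.rate, band=band)
    return float(np.max(rectify(filtered)))


def segment_trials(
    recording: EMGRecording,
    markers: list[Marker],
    phase_fractions: tuple[float, ...] = (),
    expected_trials: int | None = None,
) -> TrialSegmentation:
    """Build trial windows from trigger/activity markers.

    Markers must pair up per trial; activity markers default to the
    trigger window when absent.  A trial-count mismatch is logged, not
    fatal (the hardware occasionally drops a trigger).
    """
    n = recording.n_samples
    by_trial: dict[int, dict[str, int]] = {}
    for m in markers:
        if not (0 <= m.sample_index <= n):
            raise ValueError(
                f"marker {m.kind} of trial {m.trial_id} outside recording"
            )
        d = by_trial.setdefault(m.trial_id, {})
        if m.kind in d:
            raise ValueError(f"duplicate {m.kind} marker for trial {m.trial_id}")
        d[m.kind] = m.sample_index

    windows = []
    for tid in sorted(by_trial):
        d = by_trial[tid]
        if "trigger_start" not in d or "trigger_end" not in d:
            raise ValueError(f"trial {tid}: unpaired trigger markers")
        start, end = d["trigger_start"], d["trigger_end"]
        windows.append(
            TrialWindow(
                tid,
                start,
                end,
                d.get("activity_start", start),
                d.get("activity_end", end),
            )
        )
    if not windows:
        logger.warning("no markers: recording yields zero trials")
    if expected_trials is not None and len(windows) != expected_trials:
        logger.warning(
            "expected %d trials but markers define %d", expected_trials, len(windows)
        )
    return TrialSegmentation(tuple(windows), tuple(phase_fractions))


def resample_trials(
    trials: list[np.ndarray], target_length: int | None = None
) -> tuple[list[np.ndarray], int]:
    """Linearly resample every trial to a common length.

    The target defaults to the rounded mean trial length (the study
    aligns repetitions on the cohort-mean duration before averaging).
    Endpoints are preserved exactly.
    """
    if not trials:
        raise ValueError("no trials to resample")
    if any(len(t) < 2 for t in trials):
        raise ValueError("each trial needs at least 2 samples")
    if target_length is None:
        target_length = int(round(np.mean([len(t) for t in trials])))
    target_length = max(target_length, 2)
    out = []
    for t in trials:
        t = np.asarray(t, dtype=float)
        src = np.linspace(0.0, 1.0, len(t))
        dst = np.linspace(0.0, 1.0, target_length)
        out.append(np.interp(dst, src, t))
    return out, target_length


# ---------------------------------------------------------------------------
# file dialects


def write_emg_csv(recording: EMGRecording, path) -> None:
    """Columns: time_s, fcu_uV, ecu_uV, bb_uV, dm_uV."""
    t = np.arange(recording.n_samples) / recording.rate
    data = {"time_s": t}
    for m in MUSCLES:
        data[f"{m}_uV"] = recording.channels[m]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_emg_csv(path, rate: float | None = None) -> EMGRecording:
    df = pd.read_csv(path)
    missing = [c for c in ["time_s"] + [f"{m}_uV" for m in MUSCLES] if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path)}: missing EMG columns {missing}")
    if rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or not np.all(dt > 0):
            raise ValueError(f"{Path(path)}: cannot infer rate from time_s")
        rate = 1.0 / float(np.median(dt))
    channels = {m: df[f"{m}_uV"].to_numpy(dtype=float) for m in MUSCLES}
    return EMGRecording(rate=float(rate), channels=channels)


def write_markers_csv(markers: list[Marker], path) -> None:
    pd.DataFrame(
        [
            {"trial_id": m.trial_id, "kind": m.kind, "sample_index": m.sample_index}
            for m in markers
        ]
    ).to_csv(path, index=False)


def read_markers_csv(path) -> list[Marker]:
    df = pd.read_csv(path)
    missing = [c for c in ("trial_id", "kind", "sample_index") if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path)}: missing marker columns {missing}")
    return [
        Marker(int(r.trial_id), str(r.kind), int(r.sample_index))
        for r in df.itertuples()
    ]


def write_mvc_csv(table: MVCTable, path) -> None:
    pd.DataFrame(
        [{"muscle": m, "mvc_uV": v} for m, v in table.values.items()]
    ).to_csv(path, index=False)


def read_mvc_csv(path) -> MVCTable:
    df = pd.read_csv(path)
    missing = [c for c in ("muscle", "mvc_uV") if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path)}: missing MVC columns {missing}")
    return MVCTable({str(r.muscle): float(r.mvc_uV) for r in df.itertuples()})
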